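# voctree

Decision-tree cost-effectiveness analysis of preventive treatments for
sickle-cell-disease vaso-occlusive pain crises: crizanlizumab (5 mg/kg and
2.5 mg/kg) versus l-glutamine, from a healthcare-payer perspective over a
one-year horizon, with costs in 2021 Qatari Riyal (QAR).

The package is aimed at health-economics modellers: it provides a generic
decision-tree engine (validation, pathway enumeration, expected-value
rollback), incremental cost-effectiveness analysis (ICER, dominance and
extended dominance, net monetary benefit, frontier), and uncertainty
analysis (triangular and percentile-anchored "Trigen" distributions,
one-way sensitivity analysis, Monte-Carlo probabilistic sensitivity
analysis, acceptability curves, tornado regression), plus the concrete
published three-arm parameterization as packaged fixtures.

## The model

Each strategy arm is a decision tree. The root splits into *success* (no
first pain crisis in the year, with or without adverse events — both carry
effectiveness 1) and *failure* (first pain crisis possibly followed by a
second and an additional crisis, acute chest syndrome, death, or a residual
"other failure" branch carrying the unaccounted probability mass). For a
pathway with conditional branch probabilities p₁,…,p_k and terminal cost c,

- joint probability: P = ∏ᵢ pᵢ,
- expected cost per arm: E[C] = Σ_pathways P·c (computed by leaf-to-root
  rollback),
- effectiveness: E[e] = P(no first pain crisis),
- ICER between strategies: ΔC/ΔE in QAR per pain crisis averted, with
  dominance (ΔE > 0, ΔC < 0) reported instead of a ratio,
- net monetary benefit at willingness-to-pay λ: NMB = λ·E[e] − E[C];
  the default λ is 547,500 QAR (USD 150,000) per crisis averted.

Probabilistic sensitivity analysis draws each clinical-event probability
independently from a triangular distribution fitted to its Trigen spec
(mode plus values anchored at the 5th/95th percentiles), renormalizes
sibling branches, re-evaluates the arms, and records (ΔC, ΔE, NMB) per
iteration; acceptability curves and standardized-OLS tornado rankings are
derived from the sample set.

## Worked example

```python
>>> import voctree as vt
>>> fx = vt.load_fixtures()
>>> report = vt.reproduce_base_case(fx)
>>> for a in report.arm_results:
...     print(a.strategy, round(a.expected_cost), round(a.effectiveness, 4))
crizanlizumab_5mg 489471 0.5152
crizanlizumab_2.5mg 253550 0.5625
l_glutamine 186344 0.4503
```

Effectiveness reproduces the published ordering (l-glutamine 0.4503 <
5 mg/kg 0.5152 < 2.5 mg/kg 0.5625): the 2.5 mg/kg dose is both more
effective and cheaper than 5 mg/kg, i.e. dominant:

```python
>>> for c in report.comparisons:
...     print(c.comparator, "vs", c.reference, round(c.delta_cost),
...           round(c.delta_effect, 4), c.classification)
crizanlizumab_5mg vs l_glutamine 303127 0.0649 not_cost_effective_vs_wtp
crizanlizumab_2.5mg vs l_glutamine 67206 0.1122 not_cost_effective_vs_wtp
crizanlizumab_2.5mg vs crizanlizumab_5mg -235921 0.0473 dominant
```

Here ΔC is in QAR per patient per year and ΔE is the gain in probability of
avoiding the first crisis; e.g. 2.5 mg/kg vs l-glutamine costs 67,206 QAR
more and averts 0.1122 extra first crises per patient-year (ICER ≈ 598,982
QAR per crisis averted, just above the 547,500 QAR threshold). Note that the
expected costs and ICERs are recomputed from the published *inputs*; the
published headline ratios themselves are internally inconsistent and are
deliberately not matched (see `docs/methods.md`). The recomputed joint
pathway probabilities agree with the published table at 4 decimals wherever
the published numbers are self-consistent (e.g. 0.4431 for "success with
AEs" on 5 mg/kg); the remaining cells are flagged in
`report.discrepancies`.

The same analyses are available from a shell:

```sh
voctree base-case --out results/base
voctree owsa --out results/owsa --iterations 1000 --seed 1
voctree psa  --out results/psa  --iterations 5000 --seed 1
voctree ceac --out results/ceac --iterations 5000 --seed 1 --plot
voctree tornado --out results/tornado --iterations 5000 --seed 1
```

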