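# Methods

## Model structure and assumptions

Each treatment strategy (crizanlizumab 5 mg/kg, crizanlizumab 2.5 mg/kg,
l-glutamine) is represented as a one-year decision tree. The root chance
node splits a hypothetical adult sickle-cell-disease patient into *success*
— no first vaso-occlusive pain crisis, subdivided into with/without adverse
events, both counted as effectiveness 1 — and *failure*, subdivided into a
first pain crisis (optionally followed by a second and then an additional
crisis), acute chest syndrome (ACS), all-cause death, and a residual "other
failure" branch. Terminals carry a total annual cost (QAR/patient) and a
binary effectiveness indicator. No discounting is applied (nothing is
projected beyond one year) and no quality-of-life weighting is modelled;
the effectiveness unit is "first pain crisis averted per patient-year".

Two structural choices deserve note, both forced by internal
inconsistencies of the published parameter tables:

- **"Success" includes adverse events.** The published success-pathway rows
  ("success with AEs") are only consistent with a success definition that
  allows non-serious adverse events; the alternative reading (success
  excludes AEs) contradicts the tabulated joint probabilities and is not
  used.
- **Residual failure branch.** The published failure sub-branch
  probabilities (first crisis / ACS / death) do not complete a probability
  space (e.g. 0.92 + 0 + 0.016 = 0.936 for the 5 mg/kg arm). The tree adds
  an explicit complement branch so every chance node sums to one. Its
  terminal is costed at the arm's no-AE base cost — the least-assumption
  option, chosen once and documented here; it is a modelling choice, not a
  published figure.

All complementary probabilities (no AEs, no second crisis, no additional
crisis, failure, residual) are derived as exact complements of the sampled
or configured values, so constructed trees always validate at 1e-9. The
engine nevertheless validates probability sums explicitly because trees can
also be loaded from user configs; trees assembled directly from the
published *joint* columns (which sum to 0.9908–0.9939) validate only at a
loose 1e-2 tolerance and are flagged at 5e-3.

## What is, and is not, reproduced

Recomputing joint pathway probabilities as products of the published
conditional probabilities reproduces seven published cells exactly at four
decimals (five on the 5 mg/kg arm, the two success cells on the 2.5 mg/kg
arm; the 2.5 mg/kg success probability is taken as 0.5625, the value that
reproduces those joints, rather than the 0.56 mode listed among the
uncertainty ranges). The remaining published joints — notably every
"failure due to death" cell and most l-glutamine cells — cannot be derived
from any product of the published conditionals; they are stored verbatim
and reported as flagged discrepancies, never silently reconciled.

The published headline ICERs (79,424 / 73,226 QAR; a 3552 QAR saving), the
abstract's dollar ICERs and the "nearly 90% / 80%" acceptability fractions
are mutually inconsistent and not derivable from the published inputs: the
sum-of-products arithmetic gives ΔC ≈ 303,000 QAR and ΔE = 0.0649 for
5 mg/kg vs l-glutamine — an ICER three orders of magnitude off the headline
value, with no combination of the printed inputs bridging the gap. The
engine therefore reproduces the *arithmetic from the inputs* and the
qualitative structure (effectiveness ordering; dominance of 2.5 mg/kg over
5 mg/kg), and the test suite substitutes property-based checks against
independent brute-force oracles (enumeration vs rollback, frontier walk vs
net-monetary-benefit maximization, percentile round trips, known-coefficient
regression recovery, seed determinism) for the non-reproducible headline
numbers.

Terminal costs are taken directly from the published pathway-cost column;
they cannot be rebuilt from the published resource components (the
components sum to different totals), so the component breakdown is retained
as descriptive metadata only.

## Distributions

**Triangular.** Parameterized by (min, mode, max); sampling is by inverse
CDF applied to uniform draws, mean (a+m+b)/3, closed-form CDF/PDF/PPF.
Degenerate point masses (min = max) are permitted and used to collapse the
PSA onto the base case.

**Trigen (percentile-anchored triangular).** Specified as a most likely
value plus a bottom value at a bottom percentile and a top value at a top
percentile (here always 5/95). The support (a, b) solves
F(lower_anchor) = p_lo and F(upper_anchor) = p_hi with the given mode.
Because each one-sided condition is a quadratic in one endpoint given the
other, the solver alternates exact one-sided quadratic solves to a fixed
point (convergence threshold 1e-14 on the endpoints; the percentile
residuals are verified to 1e-9, and non-convergence or inconsistent anchors
raise an explicit infeasibility error). Anchors at percentiles 0/100 pin
the support directly. Note the convention cannot represent a distribution
whose mode lies outside the anchor percentile band; such specs are
rejected at construction.

A consequence accepted deliberately: several published uncertainty ranges
imply supports extending outside [0, 1] (both ACS rows, with bottom value 0
at the 5th percentile, put exactly 5% of their mass below zero; some
death/AE rows spill similarly). These are real properties of the published
ranges, not fitting artifacts — the percentile conditions are met to 1e-9.

## Probabilistic sensitivity analysis

Per iteration all 21 clinical-event parameters (7 per arm) are drawn
independently (no correlation structure is specified for the model);
complementary siblings are renormalized rather than sampled separately, and
failure sub-branches that sum above one are scaled back onto the simplex.
Draws that leave [0, 1] individually make the iteration invalid: it is
rejected, logged, and redrawn. Because of the out-of-range support mass
described above, the fixture model intrinsically rejects ≈19% of
iterations; the rejection cap that aborts a run as misspecified is
therefore set at 50% of the requested iterations (the cap exists to catch
genuinely degenerate specs, not the expected fixture behaviour). The
default run is 5000 iterations under an explicit caller-provided seed; a
fixed seed reproduces both the input and output matrices bit-exactly,
including rejected redraws.

Acceptability curves report, per willingness-to-pay λ on a grid (default 0
to 1,000,000 QAR in 10,000 steps, always including the 547,500 QAR
threshold), the fraction of iterations with λ·ΔE − ΔC > 0, alongside the
λ-free dominant fraction (ΔE > 0 and ΔC < 0). Tornado rankings are
standardized ordinary-least-squares coefficients of a chosen output (NMB,
ΔC or ΔE) on all sampled inputs, ranked by absolute magnitude with
alphabetical tie-breaks; constant or collinear input columns are dropped
with a warning and listed in the report.

One-way sensitivity analysis varies one parameter at a time over a
triangular range (for medication unit costs: ±15% around the point
estimate, bounds reported integer-rounded). The unit-cost multiplier
propagates into the tree by shifting every terminal cost of the affected
arm by its annual medication component times (multiplier − 1); the
published totals cannot be decomposed further, so this uniform shift is the
package's propagation choice. Summaries are the mean and 2.5/97.5
percentiles of the ICER over the draws — or of the incremental cost when
the comparison is dominance-classified in the majority of draws.

## Incremental analysis conventions

ICERs are reported per whole pain crisis averted (probability scale).
Dominance (ΔE > 0, ΔC < 0 from the comparator's perspective) and zero
effect differences are reported as classifications instead of ±infinite
ratios. The multi-strategy frontier sorts arms by effectiveness, flags
strict dominance, prunes extended dominance iteratively (an arm whose ICER
against the next-cheaper frontier member exceeds that of a more effective
member), and selects the optimum at the threshold by maximum net monetary
benefit with ties broken toward lower cost. The QAR/USD rate defaults to
3.641, back-calculated from the published QAR/USD result pairs; the
published WTP pair implies 3.65 instead, a discrepancy that is surfaced
rather than reconciled.

## Synthetic data

The synthetic generators exist so that every engine path is testable
without the packaged fixtures. `generate_synthetic_params` draws arm
parameterizations with uniformly distributed event probabilities (failure
sub-branches as a normalized 4-vector, so the residual is non-negative by
construction) and log-uniform terminal costs on [0.1, 10] × cost_scale
(default scale 100,000 QAR, the order of magnitude of the fixture
pathways); `random_tree` grows arbitrary-shape trees with normalized branch
probabilities for enumeration/rollback properties. Both are deterministic
under a seed. What these emulate is the *algebraic structure* of the model
(probability spaces, positive costs, binary effects) — not clinical
realism: passing property tests demonstrates engine correctness, not that
the fixture parameters are clinically right.

## Problem sizes and numerical choices

Property tests use 1000 random trees (rollback vs enumeration at 1e-9
relative), 500 random arm sets (frontier walk vs NMB maximization), 10⁵
draws per fitted distribution (percentile round trips, tolerance four
quantile standard errors), 5000-iteration regressions, and 200-spec Trigen
round trips at 1e-7 — sizes at which the Monte-Carlo error bounds above are
comfortably discriminating while the whole suite runs in seconds.
Probability-sum validation defaults to 1e-9 for constructed trees. Equality
of incremental deltas uses an absolute 1e-12 threshold; reporting rounds
QAR to integers and probabilities to four decimals, matching the published
display conventions, while all internal computation is double precision.

## Known limitations

- No QALY weighting, no Markov extension, no time horizon beyond one year,
  no discounting — matching the scope of the underlying model.
- Sampled parameters are independent; no copulas or Dirichlet sampling of
  whole probability vectors (only renormalization).
- The one-way unit-cost propagation assumes medication cost scales
  proportionally within each arm's published totals.
- The published headline ICERs are not reproducible from the published
  inputs; this package makes the disagreement explicit rather than fitting
  to either side.
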