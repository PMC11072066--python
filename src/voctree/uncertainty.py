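"""Uncertainty analysis: triangular and percentile-anchored (Trigen)
distributions, one-way sensitivity ranges, Monte-Carlo probabilistic
sensitivity analysis, acceptability curves, and tornado regression.

The Trigen convention follows the risk-analysis-software usage: a most
likely value plus a bottom value pinned at a bottom percentile and a top
value pinned at a top percentile.  Recovering the triangular support
requires inverting the triangular CDF on each side; the two one-sided
conditions are coupled through the support width, so they are solved by
alternating exact one-sided solves to a fixed point (residual tolerance
1e-10 on both percentile conditions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cea import DEFAULT_WTP_QAR, ArmResult, WTPThreshold, icer, net_monetary_benefit

__all__ = [
    "TriangularSpec",
    "TrigenSpec",
    "TrigenInfeasibleError",
    "InvalidSampleError",
    "PSARejectionError",
    "PSASampleSet",
    "CEACPoint",
    "TornadoEntry",
    "TornadoReport",
    "PSAModel",
    "make_owsa_range",
    "triangular_sample",
    "trigen_to_triangular",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "tornado_regression",
    "one_way_sensitivity",
]


class TrigenInfeasibleError(ValueError):
    """No triangular support satisfies the percentile anchors and mode."""


class InvalidSampleError(ValueError):
    """A sampled parameter set produced a probability outside [0, 1]."""


class PSARejectionError(RuntimeError):
    """Too many Monte-Carlo iterations rejected; inputs likely misspecified."""


@dataclass(frozen=True)
class TriangularSpec:
    """Triangular distribution by (minimum, mode, maximum).

    A degenerate spec with ``minimum == maximum`` is allowed and represents
    a point mass (samples return the constant).
    """

    minimum: float
    mode: float
    maximum: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError(
                f"triangular spec requires min <= mode <= max, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def degenerate(self) -> bool:
        return self.minimum == self.maximum

    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0

    def cdf(self, x):
        a, m, b = self.minimum, self.mode, self.maximum
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            out = (x >= a).astype(float)
            return out if out.ndim else float(out)
        out = np.zeros_like(x)
        if m > a:
            mask = (x > a) & (x <= m)
            out[mask] = (x[mask] - a) ** 2 / ((b - a) * (m - a))
        if b > m:
            mask = (x > m) & (x < b)
            out[mask] = 1.0 - (b - x[mask]) ** 2 / ((b - a) * (b - m))
        out[x >= b] = 1.0
        return out if out.ndim else float(out)

    def pdf(self, x):
        a, m, b = self.minimum, self.mode, self.maximum
        if self.degenerate:
            raise ValueError("point mass has no density")
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if m > a:
            mask = (x >= a) & (x <= m)
            out[mask] = 2.0 * (x[mask] - a) / ((b - a) * (m - a))
        if b > m:
            mask = (x > m) & (x <= b)
            out[mask] = 2.0 * (b - x[mask]) / ((b - a) * (b - m))
        return out if out.ndim else float(out)

    def ppf(self, u):
        """Inverse CDF; maps uniform draws on [0, 1] to the support."""
        a, m, b = self.minimum, self.mode, self.maximum
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("uniform draws must lie in [0, 1]")
        if self.degenerate:
            out = np.full_like(u, a)
            return out if out.ndim else float(out)
        c = (m - a) / (b - a)
        left = u <= c
        out = np.empty_like(u)
        out[left] = a + np.sqrt(u[left] * (b - a) * (m - a))
        out[~left] = b - np.sqrt((1.0 - u[~left]) * (b - a) * (b - m))
        return out if out.ndim else float(out)

    def rounded_bounds(self) -> tuple[int, int, int]:
        """(min, mode, max) rounded to the nearest integer, for reporting."""
        return (
            round(self.minimum),
            round(self.mode),
            round(self.maximum),
        )


@dataclass(frozen=True)
class TrigenSpec:
    """Percentile-anchored triangular: mode plus two percentile-pinned values.

    ``lower_anchor`` sits at ``lower_percentile`` (%) of the implied
    triangular CDF and ``upper_anchor`` at ``upper_percentile``; percentiles
    0 and 100 mean the anchors are the support itself.
    """

    lower_anchor: float
    mode: float
    upper_anchor: float
    lower_percentile: float = 5.0
    upper_percentile: float = 95.0

    def __post_init__(self) -> None:
        if not (self.lower_anchor <= self.mode <= self.upper_anchor):
            raise ValueError("trigen spec requires lower_anchor <= mode <= upper_anchor")
        if not (0.0 <= self.lower_percentile < self.upper_percentile <= 100.0):
            raise ValueError("percentiles must satisfy 0 <= lower < upper <= 100")


def make_owsa_range(point_estimate: float, fraction: float) -> TriangularSpec:
    """Symmetric +/-fraction triangular range around a point estimate.

    The convention used for one-way sensitivity on medication unit costs:
    minimum = (1 - fraction) x point, mode = point, maximum = (1 + fraction)
    x point.  Report bounds via :meth:`TriangularSpec.rounded_bounds`.
    """
    if not (point_estimate > 0.0):
        raise ValueError("point estimate must be positive")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    return TriangularSpec(
        minimum=point_estimate * (1.0 - fraction),
        mode=point_estimate,
        maximum=point_estimate * (1.0 + fraction),
    )


def triangular_sample(spec: TriangularSpec, rng: np.random.Generator, size=None):
    """Draw from a triangular distribution by inverse-CDF of uniform draws."""
    u = rng.random(size)
    return spec.ppf(u)


def _solve_lower(L: float, m: float, b: float, p: float) -> float:
    """Support minimum a with CDF(L) = p for fixed maximum b (L <= m, p > 0)."""
    if L == m:
        # F(m) = (m - a) / (b - a) = p
        return (m - p * b) / (1.0 - p)
    # (L - a)^2 = p (b - a)(m - a): quadratic in a, valid root is below L
    A = 1.0 - p
    B = p * (b + m) - 2.0 * L
    C = L * L - p * b * m
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise TrigenInfeasibleError("no real support minimum for the lower anchor")
    root = (-B - math.sqrt(disc)) / (2.0 * A)
    if root > L + 1e-12:
        raise TrigenInfeasibleError("lower anchor inconsistent with mode")
    return root


def _solve_upper(U: float, m: float, a: float, p_hi: float) -> float:
    """Support maximum b with CDF(U) = p_hi for fixed minimum a (U >= m)."""
    q = 1.0 - p_hi
    if q <= 0.0:
        return U
    if U == m:
        # F(m) = (m - a)/(b - a) = p_hi  =>  b = a + (m - a)/p_hi
        if p_hi <= 0.0:
            raise TrigenInfeasibleError("upper anchor at mode needs a positive percentile")
        return a + (m - a) / p_hi
    # (b - U)^2 = q (b - a)(b - m): quadratic in b, valid root is above U
    A = 1.0 - q
    B = q * (a + m) - 2.0 * U
    C = U * U - q * a * m
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise TrigenInfeasibleError("no real support maximum for the upper anchor")
    root = (-B + math.sqrt(disc)) / (2.0 * A)
    if root < U - 1e-12:
        raise TrigenInfeasibleError("upper anchor inconsistent with mode")
    return root


def trigen_to_triangular(
    spec: TrigenSpec, tol: float = 1e-10, max_iter: int = 500
) -> TriangularSpec:
    """Recover the triangular support implied by a Trigen spec.

    Finds the unique (min, mode, max) whose CDF equals
    ``lower_percentile/100`` at the lower anchor and ``upper_percentile/100``
    at the upper anchor.  Percentile 0 (100) pins the minimum (maximum) to
    the anchor directly.  Raises :class:`TrigenInfeasibleError` when no
    support is consistent with the anchors and mode.
    """
    L, m, U = spec.lower_anchor, spec.mode, spec.upper_anchor
    p_lo = spec.lower_percentile / 100.0
    p_hi = spec.upper_percentile / 100.0
    if L == U:
        # a zero-width anchor band cannot place distinct percentiles
        raise TrigenInfeasibleError("anchors coincide; no feasible support")

    a = L
    b = U
    for _ in range(max_iter):
        a_new = _solve_lower(L, m, b, p_lo) if p_lo > 0.0 else L
        b_new = _solve_upper(U, m, a_new, p_hi) if p_hi < 1.0 else U
        if abs(a_new - a) < 1e-14 and abs(b_new - b) < 1e-14:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    fitted = TriangularSpec(a, m, b)
    resid_lo = abs(float(fitted.cdf(L)) - p_lo)
    resid_hi = abs(float(fitted.cdf(U)) - p_hi)
    if resid_lo > tol * 10 or resid_hi > tol * 10:
        raise TrigenInfeasibleError(
            f"percentile conditions not met (residuals {resid_lo:.2e}, {resid_hi:.2e})"
        )
    return fitted


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


class PSAModel(Protocol):
    """A parameterized multi-arm model evaluable at sampled inputs."""

    def evaluate(self, values: Mapping[str, float]) -> Sequence[ArmResult]:
        """Return one ArmResult per strategy; raise InvalidSampleError when a
        sampled probability leaves [0, 1] after renormalization."""
        ...


@dataclass
class PSASampleSet:
    """Inputs and incremental outputs of a Monte-Carlo PSA run.

    ``input_matrix`` is iterations x parameters (columns follow
    ``parameter_names``); for each comparison label ``"comp vs ref"`` the
    output arrays hold per-iteration (delta cost, delta effect, NMB
    difference at the run's WTP).
    """

    seed: int
    n_iterations: int
    wtp: WTPThreshold
    parameter_names: list[str]
    comparison_labels: list[str]
    input_matrix: np.ndarray
    delta_cost: np.ndarray  # iterations x comparisons
    delta_effect: np.ndarray
    nmb: np.ndarray
    n_rejected: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.input_matrix, columns=self.parameter_names)
        for j, label in enumerate(self.comparison_labels):
            df[f"delta_cost[{label}]"] = self.delta_cost[:, j]
            df[f"delta_effect[{label}]"] = self.delta_effect[:, j]
            df[f"nmb[{label}]"] = self.nmb[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def _column(self, comparison: str | None) -> int:
        if comparison is None:
            return 0
        return self.comparison_labels.index(comparison)


@dataclass(frozen=True)
class CEACPoint:
    """One point of a cost-effectiveness acceptability curve."""

    wtp: float
    probability_cost_effective: float
    probability_dominant: float


@dataclass(frozen=True)
class TornadoEntry:
    """One input's standardized regression coefficient and its rank."""

    parameter: str
    standardized_coefficient: float
    rank: int


@dataclass
class TornadoReport:
    """Ranked tornado entries plus any inputs dropped before regression."""

    output: str
    comparison: str
    entries: list[TornadoEntry] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def run_psa(
    model: PSAModel,
    specs: Mapping[str, TriangularSpec | TrigenSpec],
    n: int,
    seed: int,
    wtp: WTPThreshold | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
    max_reject_frac: float = 0.5,
) -> PSASampleSet:
    """Monte-Carlo probabilistic sensitivity analysis.

    Per iteration every parameter in ``specs`` is drawn independently from
    its (fitted) triangular distribution and the model re-evaluated;
    iterations whose sampled probabilities leave [0, 1] after sibling
    renormalization are rejected and redrawn (the model signals this with
    :class:`InvalidSampleError`).  Rejections beyond ``max_reject_frac * n``
    abort with a diagnostic.  Fully deterministic under a fixed seed.

    ``comparisons`` lists (comparator, reference) strategy names; when
    omitted, ``model.default_comparisons`` is used if present, else all
    unordered strategy pairs in base-result order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = sorted(specs)
    triangulars = {
        name: (
            trigen_to_triangular(s) if isinstance(s, TrigenSpec) else s
        )
        for name, s in ((name, specs[name]) for name in names)
    }

    base_arms = list(model.evaluate({}))
    wtp = wtp or WTPThreshold(currency=base_arms[0].currency)
    if comparisons is None:
        comparisons = getattr(model, "default_comparisons", None)
    if comparisons is None:
        comparisons = [
            (base_arms[j].strategy, base_arms[i].strategy)
            for i in range(len(base_arms))
            for j in range(i + 1, len(base_arms))
        ]
    comparisons = list(comparisons)
    labels = [f"{comp} vs {ref}" for comp, ref in comparisons]

    rng = np.random.default_rng(seed)
    max_reject = max(int(max_reject_frac * n), 1)
    inputs = np.empty((n, len(names)))
    dc = np.empty((n, len(comparisons)))
    de = np.empty((n, len(comparisons)))
    nmb = np.empty((n, len(comparisons)))
    rejected = 0
    i = 0
    while i < n:
        row = np.array([triangulars[name].ppf(rng.random()) for name in names])
        try:
            arms = {a.strategy: a for a in model.evaluate(dict(zip(names, row)))}
        except InvalidSampleError:
            rejected += 1
            if rejected > max_reject:
                raise PSARejectionError(
                    f"{rejected} rejected iterations exceed the cap "
                    f"({max_reject_frac:.0%} of n={n}); check the distribution specs"
                )
            continue
        inputs[i] = row
        for j, (comp, ref) in enumerate(comparisons):
            dc[i, j] = arms[comp].expected_cost - arms[ref].expected_cost
            de[i, j] = arms[comp].effectiveness - arms[ref].effectiveness
            nmb[i, j] = net_monetary_benefit(arms[comp], wtp) - net_monetary_benefit(
                arms[ref], wtp
            )
        i += 1
    return PSASampleSet(
        seed=seed,
        n_iterations=n,
        wtp=wtp,
        parameter_names=names,
        comparison_labels=labels,
        input_matrix=inputs,
        delta_cost=dc,
        delta_effect=de,
        nmb=nmb,
        n_rejected=rejected,
    )


def default_wtp_grid(
    maximum: float = 1_000_000.0,
    step: float = 10_000.0,
    include: float | None = DEFAULT_WTP_QAR,
) -> np.ndarray:
    """0 to ``maximum`` in ``step`` increments, always including ``include``."""
    grid = np.arange(0.0, maximum + step / 2, step)
    if include is not None and include not in grid:
        grid = np.sort(np.append(grid, include))
    return grid


def ceac(
    samples: PSASampleSet,
    wtp_grid: Sequence[float],
    comparison: str | None = None,
) -> list[CEACPoint]:
    """Acceptability curve for one comparison across a WTP grid.

    At each threshold lambda the curve reports the fraction of iterations
    with positive incremental net benefit (lambda x dE - dC > 0); the
    dominant fraction (dE > 0 and dC < 0) is constant in lambda.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    j = samples._column(comparison)
    dc = samples.delta_cost[:, j]
    de = samples.delta_effect[:, j]
    p_dom = float(np.mean((de > 0) & (dc < 0)))
    points = []
    for lam in wtp_grid:
        p_ce = float(np.mean(lam * de - dc > 0))
        points.append(CEACPoint(float(lam), p_ce, p_dom))
    return points


def tornado_regression(
    samples: PSASampleSet,
    output: str = "nmb",
    comparison: str | None = None,
) -> TornadoReport:
    """Standardized OLS of a PSA output on all sampled inputs.

    Inputs and output are z-scored, so coefficients are comparable across
    parameters; entries are ranked by descending absolute coefficient, ties
    broken alphabetically.  Constant or collinear input columns are dropped
    with a warning and listed in the report.
    """
    column = {"delta_cost": samples.delta_cost, "delta_effect": samples.delta_effect,
              "nmb": samples.nmb}
    if output not in column:
        raise ValueError(f"unknown output selector {output!r}")
    j = samples._column(comparison)
    y = column[output][:, j]
    X = samples.input_matrix
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more iterations than parameters + 1")

    names = list(samples.parameter_names)
    dropped = []

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    for name, k in zip(names, keep):
        if not k:
            dropped.append(name)
    X = X[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    # drop columns that do not increase rank (collinearity)
    if Z.shape[1] and np.linalg.matrix_rank(Z) < Z.shape[1]:
        kept_idx: list[int] = []
        for k in range(Z.shape[1]):
            trial = Z[:, kept_idx + [k]]
            if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
                kept_idx.append(k)
            else:
                dropped.append(names[k])
        Z = Z[:, kept_idx]
        names = [names[k] for k in kept_idx]
    if dropped:
        warnings.warn(
            f"tornado regression dropped columns: {sorted(dropped)}", stacklevel=2
        )

    y_sd = y.std(ddof=1)
    report = TornadoReport(output=output, comparison=samples.comparison_labels[j],
                           dropped=sorted(dropped))
    if y_sd == 0 or not names:
        return report
    yz = (y - y.mean()) / y_sd
    fit = sm.OLS(yz, Z).fit()
    coefs = sorted(zip(names, fit.params), key=lambda t: (-abs(t[1]), t[0]))
    report.entries = [
        TornadoEntry(parameter=nm, standardized_coefficient=float(c), rank=r)
        for r, (nm, c) in enumerate(coefs, start=1)
    ]
    return report


def one_way_sensitivity(
    model: PSAModel,
    specs: Mapping[str, TriangularSpec],
    n: int,
    seed: int,
    wtp: WTPThreshold | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis: vary each parameter alone.

    For each parameter, ``n`` Monte-Carlo draws from its triangular range
    re-evaluate the model with every other input at base value.  Per
    comparison the ICER's mean and 2.5/97.5 percentiles are reported when
    the ICER is defined across draws; under dominance the incremental cost
    (cost saving) is summarized instead.
    """
    base_arms = list(model.evaluate({}))
    wtp = wtp or WTPThreshold(currency=base_arms[0].currency)
    if comparisons is None:
        comparisons = getattr(model, "default_comparisons", None) or [
            (base_arms[j].strategy, base_arms[i].strategy)
            for i in range(len(base_arms))
            for j in range(i + 1, len(base_arms))
        ]
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(specs):
        spec = specs[name]
        draws = np.atleast_1d(triangular_sample(spec, rng, size=n))
        results: dict[tuple[str, str], list] = {tuple(c): [] for c in comparisons}
        for value in draws:
            arms = {a.strategy: a for a in model.evaluate({name: float(value)})}
            for comp, ref in comparisons:
                results[(comp, ref)].append(icer(arms[ref], arms[comp], wtp))
        for comp, ref in comparisons:
            incs = results[(comp, ref)]
            icers = np.array([r.icer for r in incs if r.icer is not None])
            if icers.size >= len(incs) / 2:
                series, quantity = icers, "icer"
            else:
                series = np.array([r.delta_cost for r in incs])
                quantity = "delta_cost"
            rows.append(
                {
                    "parameter": name,
                    "comparison": f"{comp} vs {ref}",
                    "quantity": quantity,
                    "mean": float(series.mean()),
                    "p2.5": float(np.percentile(series, 2.5)),
                    "p97.5": float(np.percentile(series, 97.5)),
                    "n_dominant": sum(r.classification == "dominant" for r in incs),
                    "n": len(incs),
                }
            )
    return pd.DataFrame(rows)
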