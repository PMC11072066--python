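"""Three-arm sickle-cell-disease model: concrete arm parameterization,
decision-tree construction, base-case reproduction, and synthetic parameter
generation for property testing.

The packaged fixtures hold the published inputs for the three strategies
(crizanlizumab 5 mg/kg, crizanlizumab 2.5 mg/kg, l-glutamine): conditional
clinical-event probabilities, pathway total costs in QAR per patient per
year, Trigen uncertainty ranges, medication unit costs, and the
willingness-to-pay threshold.  Joint pathway probabilities are always
recomputed from the conditionals; the as-published joint values are carried
along purely as cross-check targets, because they do not all sum to one.

Each arm's tree: a root success/failure split; success divides into
with/without adverse events (both effectiveness 1, "no first pain crisis");
failure divides into first pain crisis (which may chain into a second and
an additional crisis), acute chest syndrome, death, and an explicit
residual "other failure" branch that carries the probability mass the
published failure sub-branches leave unaccounted.  The residual terminal is
costed at the arm's no-AE base cost -- a modelling choice, the least
assumption available, not a published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cea import (
    ArmResult,
    FrontierResult,
    IncrementalResult,
    WTPThreshold,
    icer,
    incremental_frontier,
)
from .tree import Branch, ChanceNode, DecisionTree, TerminalNode, enumerate_pathways, expected_value
from .uncertainty import InvalidSampleError, TriangularSpec, TrigenSpec, make_owsa_range

__all__ = [
    "PATHWAY_LABELS",
    "PROBABILITY_FIELDS",
    "ArmParameters",
    "FixtureSet",
    "ThreeArmModel",
    "BaseCaseReport",
    "SyntheticModelSpec",
    "load_fixtures",
    "load_model_config",
    "build_arm_tree",
    "reproduce_base_case",
    "generate_synthetic_params",
    "random_tree",
]

#: Terminal pathway labels in published-table order, plus the residual.
PATHWAY_LABELS = (
    "success_with_aes",
    "success_without_aes",
    "additional_crisis",
    "no_additional_crisis",
    "no_second_crisis",
    "acs",
    "death",
    "other_failure",
)

PROBABILITY_FIELDS = (
    "p_success",
    "p_ae_given_success",
    "p_first_crisis_given_failure",
    "p_second_given_first",
    "p_additional_given_second",
    "p_acs_given_failure",
    "p_death_given_failure",
)


@dataclass(frozen=True)
class ArmParameters:
    """Conditional event probabilities and terminal costs for one strategy."""

    strategy: str
    p_success: float
    p_ae_given_success: float
    p_first_crisis_given_failure: float
    p_second_given_first: float
    p_additional_given_second: float
    p_acs_given_failure: float
    p_death_given_failure: float
    terminal_costs: dict[str, float]
    medication_annual_cost: float | None = None
    medication_unit_cost: float | None = None

    def probabilities(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PROBABILITY_FIELDS}


def build_arm_tree(params: ArmParameters) -> DecisionTree:
    """Construct the arm's decision tree from its conditional probabilities.

    Complementary branches (no AEs, no second crisis, no additional crisis,
    failure, residual failure) are derived as exact complements so every
    chance node is a probability space by construction.  Raises
    :class:`InvalidSampleError` when any conditional leaves [0, 1] or the
    failure sub-branches exceed probability one, and ``KeyError`` when a
    pathway label is missing from ``terminal_costs``.
    """
    for name, p in params.probabilities().items():
        if not (0.0 <= p <= 1.0):
            raise InvalidSampleError(f"{params.strategy}: {name}={p} outside [0, 1]")
    residual = 1.0 - (
        params.p_first_crisis_given_failure
        + params.p_acs_given_failure
        + params.p_death_given_failure
    )
    if residual < -1e-12:
        raise InvalidSampleError(
            f"{params.strategy}: failure sub-branch probabilities sum above 1"
        )
    residual = max(residual, 0.0)

    missing = [l for l in PATHWAY_LABELS if l not in params.terminal_costs]
    if missing:
        raise KeyError(f"{params.strategy}: missing terminal cost for {missing}")

    def term(label: str, effect: float) -> TerminalNode:
        return TerminalNode(label, params.terminal_costs[label], effect)

    second_node = ChanceNode(
        "second_crisis",
        [
            Branch(
                "additional_crisis",
                params.p_additional_given_second,
                term("additional_crisis", 0),
            ),
            Branch(
                "no_additional_crisis",
                1.0 - params.p_additional_given_second,
                term("no_additional_crisis", 0),
            ),
        ],
    )
    first_node = ChanceNode(
        "first_crisis",
        [
            Branch("second_crisis", params.p_second_given_first, second_node),
            Branch(
                "no_second_crisis",
                1.0 - params.p_second_given_first,
                term("no_second_crisis", 0),
            ),
        ],
    )
    failure_node = ChanceNode(
        "failure",
        [
            Branch("first_crisis", params.p_first_crisis_given_failure, first_node),
            Branch("acs", params.p_acs_given_failure, term("acs", 0)),
            Branch("death", params.p_death_given_failure, term("death", 0)),
            Branch("other_failure", residual, term("other_failure", 0)),
        ],
    )
    success_node = ChanceNode(
        "success",
        [
            Branch("with_aes", params.p_ae_given_success, term("success_with_aes", 1)),
            Branch(
                "without_aes",
                1.0 - params.p_ae_given_success,
                term("success_without_aes", 1),
            ),
        ],
    )
    root = ChanceNode(
        params.strategy,
        [
            Branch("success", params.p_success, success_node),
            Branch("failure", 1.0 - params.p_success, failure_node),
        ],
    )
    return DecisionTree(params.strategy, root)


# ---------------------------------------------------------------------------
# fixtures

_TOP_KEYS = {
    "schema_version",
    "currency",
    "wtp_qar",
    "qar_per_usd",
    "owsa_fraction",
    "medication_unit_cost",
    "arms",
}
_ARM_KEYS = set(PROBABILITY_FIELDS) | {
    "medication_annual_cost",
    "medication_unit_cost",
    "terminal_costs",
    "printed_pathway_probabilities",
    "trigen",
    "resource_costs",
}


@dataclass
class FixtureSet:
    """The packaged three-arm parameterization and its uncertainty specs."""

    arms: dict[str, ArmParameters]
    trigen: dict[str, dict[str, TrigenSpec]]
    printed_pathway_probabilities: dict[str, dict[str, float | None]]
    resource_costs: dict[str, dict[str, float]]
    medication_unit_cost: dict[str, float]
    wtp_qar: float
    qar_per_usd: float
    owsa_fraction: float
    currency: str = "QAR"

    @property
    def wtp(self) -> WTPThreshold:
        return WTPThreshold(self.wtp_qar, self.currency)

    def model(self) -> "ThreeArmModel":
        return ThreeArmModel(self.arms, currency=self.currency)

    def psa_specs(self) -> dict[str, TrigenSpec]:
        """Sampled clinical-event parameters, keyed ``"<arm>.<field>"``."""
        return {
            f"{arm}.{name}": spec
            for arm, specs in self.trigen.items()
            for name, spec in specs.items()
        }

    def owsa_specs(self, fraction: float | None = None) -> dict[str, TriangularSpec]:
        """+/-fraction triangular ranges on the medication unit costs."""
        fraction = self.owsa_fraction if fraction is None else fraction
        return {
            f"{group}.medication_unit_cost": make_owsa_range(cost, fraction)
            for group, cost in self.medication_unit_cost.items()
        }

    def point_specs(self) -> dict[str, TriangularSpec]:
        """Degenerate (point-mass) specs at every arm's base-case values."""
        return {
            f"{arm}.{name}": TriangularSpec(p, p, p)
            for arm, params in self.arms.items()
            for name, p in params.probabilities().items()
        }


def _parse_fixture_dict(data: dict) -> FixtureSet:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = _TOP_KEYS - set(data)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    if data["schema_version"] != 1:
        raise ValueError(f"unsupported schema_version {data['schema_version']!r}")

    arms: dict[str, ArmParameters] = {}
    trigen: dict[str, dict[str, TrigenSpec]] = {}
    printed: dict[str, dict[str, float | None]] = {}
    resources_: dict[str, dict[str, float]] = {}
    for arm_name, raw in data["arms"].items():
        unknown = set(raw) - _ARM_KEYS
        if unknown:
            raise ValueError(f"arm {arm_name!r}: unknown keys {sorted(unknown)}")
        arms[arm_name] = ArmParameters(
            strategy=arm_name,
            terminal_costs={k: float(v) for k, v in raw["terminal_costs"].items()},
            medication_annual_cost=float(raw["medication_annual_cost"]),
            medication_unit_cost=float(raw["medication_unit_cost"]),
            **{f: float(raw[f]) for f in PROBABILITY_FIELDS},
        )
        trigen[arm_name] = {
            name: TrigenSpec(row[0], row[1], row[2], row[3], row[4])
            for name, row in raw.get("trigen", {}).items()
        }
        printed[arm_name] = {
            k: (None if v is None else float(v))
            for k, v in raw.get("printed_pathway_probabilities", {}).items()
        }
        resources_[arm_name] = {k: float(v) for k, v in raw.get("resource_costs", {}).items()}

    return FixtureSet(
        arms=arms,
        trigen=trigen,
        printed_pathway_probabilities=printed,
        resource_costs=resources_,
        medication_unit_cost={k: float(v) for k, v in data["medication_unit_cost"].items()},
        wtp_qar=float(data["wtp_qar"]),
        qar_per_usd=float(data["qar_per_usd"]),
        owsa_fraction=float(data["owsa_fraction"]),
        currency=str(data["currency"]),
    )


def load_fixtures() -> FixtureSet:
    """Load the packaged published parameterization."""
    text = resources.files("voctree.data").joinpath("fixtures.yaml").read_text()
    return _parse_fixture_dict(yaml.safe_load(text))


def load_model_config(path: str | Path) -> FixtureSet:
    """Load a user model config in the fixtures schema; unknown keys error."""
    return _parse_fixture_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# the parameterized model used by PSA / OWSA


def _renormalize_failure_branches(params: ArmParameters) -> ArmParameters:
    """Scale the failure sub-branches back onto the simplex when sampled
    values sum above one (keeping each chance node a probability space);
    individually out-of-range values are left for rejection downstream."""
    total = (
        params.p_first_crisis_given_failure
        + params.p_acs_given_failure
        + params.p_death_given_failure
    )
    if total <= 1.0 or not all(
        0.0 <= p <= 1.0
        for p in (
            params.p_first_crisis_given_failure,
            params.p_acs_given_failure,
            params.p_death_given_failure,
        )
    ):
        return params
    return replace(
        params,
        p_first_crisis_given_failure=params.p_first_crisis_given_failure / total,
        p_acs_given_failure=params.p_acs_given_failure / total,
        p_death_given_failure=params.p_death_given_failure / total,
    )


class ThreeArmModel:
    """Multi-arm model evaluable at overridden parameter values.

    Override keys are ``"<arm>.<probability field>"`` for clinical events
    and ``"<group>.medication_unit_cost"`` for medication unit costs (group
    ``crizanlizumab`` covers both dose arms; the unit-cost multiplier shifts
    every terminal cost of the arm by its annual medication component).
    Unknown keys are errors; sampled probabilities outside [0, 1] (or
    failure sub-branches summing above 1) raise
    :class:`~voctree.uncertainty.InvalidSampleError`.
    """

    def __init__(self, arms: dict[str, ArmParameters], currency: str = "QAR"):
        self.arms = dict(arms)
        self.currency = currency
        self.default_comparisons = self._default_comparisons()

    def _default_comparisons(self) -> list[tuple[str, str]]:
        names = list(self.arms)
        base = {n: expected_value(build_arm_tree(p), "effect") for n, p in self.arms.items()}
        ordered = sorted(names, key=lambda n: base[n])
        pairs = []
        for i, ref in enumerate(ordered):
            for comp in ordered[i + 1 :]:
                pairs.append((comp, ref))
        return pairs

    def _group(self, arm_name: str) -> str:
        return "crizanlizumab" if arm_name.startswith("crizanlizumab") else arm_name

    def evaluate(self, values=None) -> list[ArmResult]:
        values = dict(values or {})
        known_prob = {
            f"{arm}.{f}" for arm in self.arms for f in PROBABILITY_FIELDS
        }
        known_cost = {f"{self._group(arm)}.medication_unit_cost" for arm in self.arms}
        unknown = set(values) - known_prob - known_cost
        if unknown:
            raise ValueError(f"parameters map to no model slot: {sorted(unknown)}")

        results = []
        for arm_name, base in self.arms.items():
            overrides = {
                f: values[f"{arm_name}.{f}"]
                for f in PROBABILITY_FIELDS
                if f"{arm_name}.{f}" in values
            }
            params = replace(base, **overrides) if overrides else base
            params = _renormalize_failure_branches(params)

            cost_key = f"{self._group(arm_name)}.medication_unit_cost"
            if cost_key in values:
                if not base.medication_unit_cost or base.medication_annual_cost is None:
                    raise ValueError(f"{arm_name}: no medication cost slot to vary")
                mult = values[cost_key] / base.medication_unit_cost
                shift = base.medication_annual_cost * (mult - 1.0)
                params = replace(
                    params,
                    terminal_costs={
                        k: max(v + shift, 0.0) for k, v in params.terminal_costs.items()
                    },
                )
            tree = build_arm_tree(params)
            results.append(
                ArmResult(
                    strategy=arm_name,
                    expected_cost=expected_value(tree, "cost"),
                    effectiveness=expected_value(tree, "effect"),
                    currency=self.currency,
                )
            )
        return results


# ---------------------------------------------------------------------------
# base-case reproduction


@dataclass
class BaseCaseReport:
    """Deterministic base-case results with published-value cross-checks."""

    pathways: pd.DataFrame
    arm_results: list[ArmResult]
    comparisons: list[IncrementalResult]
    frontier: FrontierResult

    @property
    def discrepancies(self) -> pd.DataFrame:
        flagged = self.pathways[self.pathways["agrees_at_4dp"] == False]  # noqa: E712
        return flagged[flagged["printed_probability"].notna()]


def reproduce_base_case(fixtures: FixtureSet) -> BaseCaseReport:
    """Evaluate the three arms and cross-check against the published joints.

    Pathway probabilities are recomputed from the conditionals (the product
    rule); per cell the report states whether the 4-dp rounding agrees with
    the published value and, if not, the discrepancy magnitude.  Pairwise
    incremental results and the WTP frontier come from the recomputed
    expected values only.
    """
    model = fixtures.model()
    arm_results = model.evaluate({})

    rows = []
    for arm_name, params in fixtures.arms.items():
        tree = build_arm_tree(params)
        printed = fixtures.printed_pathway_probabilities.get(arm_name, {})
        for pw in enumerate_pathways(tree):
            label = pw.terminal.name
            p4 = round(pw.joint_probability, 4)
            pub = printed.get(label)
            rows.append(
                {
                    "arm": arm_name,
                    "pathway": label,
                    "probability": pw.joint_probability,
                    "probability_4dp": p4,
                    "total_cost": pw.terminal.total_cost,
                    "weighted_cost": pw.joint_probability * pw.terminal.total_cost,
                    "printed_probability": pub,
                    "agrees_at_4dp": (pub is not None and p4 == round(pub, 4)),
                    "discrepancy": (None if pub is None else p4 - pub),
                }
            )
    pathways = pd.DataFrame(rows)

    wtp = fixtures.wtp
    by_name = {a.strategy: a for a in arm_results}
    comparisons = [
        icer(by_name[ref], by_name[comp], wtp)
        for comp, ref in model.default_comparisons
    ]
    frontier = incremental_frontier(arm_results, wtp)
    return BaseCaseReport(
        pathways=pathways,
        arm_results=arm_results,
        comparisons=comparisons,
        frontier=frontier,
    )


# ---------------------------------------------------------------------------
# synthetic generators


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Controls for the synthetic arm-parameter generator."""

    seed: int
    n_arms: int = 3
    cost_scale: float = 1e5

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        if not (self.cost_scale > 0):
            raise ValueError("cost_scale must be positive")


def _log_uniform(rng: np.random.Generator, low: float, high: float, size=None):
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def generate_synthetic_params(
    spec: SyntheticModelSpec, rng: np.random.Generator | None = None
) -> list[ArmParameters]:
    """Random valid arm parameterizations; deterministic under the seed.

    Chance-node probabilities are drawn uniformly (failure sub-branches as a
    normalized 4-vector so the residual is non-negative by construction) and
    terminal costs log-uniformly on [0.1, 10] x ``cost_scale``; every
    generated arm builds a tree that validates at 1e-9.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_arms):
        sub = rng.uniform(0.05, 1.0, size=4)
        sub = sub / sub.sum()  # first crisis, ACS, death, residual
        costs = dict(
            zip(
                PATHWAY_LABELS,
                _log_uniform(rng, 0.1, 10.0, size=len(PATHWAY_LABELS)) * spec.cost_scale,
            )
        )
        out.append(
            ArmParameters(
                strategy=f"synthetic_arm_{i}",
                p_success=float(rng.uniform(0.05, 0.95)),
                p_ae_given_success=float(rng.uniform()),
                p_first_crisis_given_failure=float(sub[0]),
                p_second_given_first=float(rng.uniform()),
                p_additional_given_second=float(rng.uniform()),
                p_acs_given_failure=float(sub[1]),
                p_death_given_failure=float(sub[2]),
                terminal_costs={k: float(v) for k, v in costs.items()},
            )
        )
    return out


def random_tree(
    rng: np.random.Generator,
    depth: int = 3,
    max_branches: int = 3,
    cost_scale: float = 1e5,
) -> DecisionTree:
    """A random valid decision tree for engine property tests.

    Branch probabilities at each chance node are normalized uniform draws
    (sum exactly to one up to floating round-off); terminal costs are
    log-uniform and effects random indicators.  ``depth`` bounds the longest
    chain of chance nodes.
    """
    counter = {"n": 0}

    def fresh(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix}_{counter['n']}"

    def grow(level: int):
        if level >= depth or (level > 0 and rng.random() < 0.3):
            return TerminalNode(
                fresh("t"),
                float(_log_uniform(rng, 0.1, 10.0)) * cost_scale,
                float(rng.integers(0, 2)),
            )
        k = int(rng.integers(2, max_branches + 1))
        probs = rng.uniform(0.05, 1.0, size=k)
        probs = probs / probs.sum()
        branches = [
            Branch(fresh("b"), float(p), grow(level + 1)) for p in probs
        ]
        return ChanceNode(fresh("n"), branches)

    root = grow(0)
    if isinstance(root, TerminalNode):  # ensure at least one chance node
        other = TerminalNode(fresh("t"), float(_log_uniform(rng, 0.1, 10.0)) * cost_scale, 0.0)
        root = ChanceNode(fresh("n"), [Branch("a", 0.5, root), Branch("b", 0.5, other)])
    return DecisionTree(fresh("tree"), root)
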