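"""Generic decision-tree model: chance and terminal nodes, validation,
pathway enumeration and expected-value evaluation.

A tree is a finite, acyclic arrangement of :class:`ChanceNode` objects whose
branches carry conditional probabilities and end in :class:`TerminalNode`
payoffs (a per-patient cost and a binary effectiveness indicator).  The
expected value of a payoff under the tree is the probability-weighted sum
over root-to-terminal pathways; it is computed by leaf-to-root rollback,
which agrees with explicit pathway enumeration up to floating round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Union

__all__ = [
    "Branch",
    "ChanceNode",
    "TerminalNode",
    "DecisionTree",
    "Pathway",
    "ValidationReport",
    "TreeStructureError",
    "validate_tree",
    "enumerate_pathways",
    "pathway_probability",
    "expected_value",
]


class TreeStructureError(ValueError):
    """A malformed tree: cycle, childless chance node, or bad node type.

    Distinct from a probability-sum violation, which is reported through
    :class:`ValidationReport` rather than raised.
    """


@dataclass(frozen=True)
class TerminalNode:
    """A leaf carrying the pathway payoffs.

    Parameters
    ----------
    name : str
        Pathway label (e.g. ``"success_with_aes"``).
    total_cost : float
        Total cost accrued on this pathway, in currency units per patient
        over the model horizon.  Must be non-negative.
    effect : float
        Binary effectiveness indicator; 1 means the outcome of interest was
        achieved (here: no first pain crisis), 0 otherwise.
    """

    name: str
    total_cost: float
    effect: float

    def __post_init__(self) -> None:
        if not (self.total_cost >= 0.0):
            raise ValueError(f"terminal {self.name!r}: total_cost must be >= 0")
        if self.effect not in (0, 1):
            raise ValueError(f"terminal {self.name!r}: effect must be 0 or 1")


Node = Union["ChanceNode", TerminalNode]


@dataclass(frozen=True)
class Branch:
    """One labelled branch of a chance node with its conditional probability."""

    label: str
    probability: float
    child: Node

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"branch {self.label!r}: probability {self.probability} not in [0, 1]"
            )


@dataclass(frozen=True)
class ChanceNode:
    """A chance node whose branches partition the event space."""

    name: str
    branches: tuple[Branch, ...]

    def __init__(self, name: str, branches) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "branches", tuple(branches))

    def probability_sum(self) -> float:
        return math.fsum(b.probability for b in self.branches)


@dataclass(frozen=True)
class DecisionTree:
    """A named decision tree for one strategy arm."""

    name: str
    root: Node


@dataclass(frozen=True)
class Pathway:
    """A root-to-terminal route with its joint probability."""

    branch_labels: tuple[str, ...]
    joint_probability: float
    terminal: TerminalNode


@dataclass
class ValidationReport:
    """Outcome of probability validation.

    ``violations`` holds ``(node_name, probability_sum, tolerance)`` for each
    chance node whose branch probabilities deviate from 1 by more than the
    tolerance; ``valid`` is true iff the list is empty.
    """

    valid: bool
    violations: list[tuple[str, float, float]] = field(default_factory=list)


def _check_structure(tree: DecisionTree) -> None:
    """Raise :class:`TreeStructureError` on cycles, childless chance nodes,
    single-branch chance nodes, or unknown node types."""
    on_path: set[int] = set()

    def visit(node: Node) -> None:
        if isinstance(node, TerminalNode):
            return
        if not isinstance(node, ChanceNode):
            raise TreeStructureError(f"unknown node type: {type(node).__name__}")
        if id(node) in on_path:
            raise TreeStructureError(f"cycle detected at node {node.name!r}")
        if len(node.branches) < 2:
            raise TreeStructureError(
                f"chance node {node.name!r} has {len(node.branches)} branch(es); need >= 2"
            )
        on_path.add(id(node))
        for branch in node.branches:
            visit(branch.child)
        on_path.discard(id(node))

    visit(tree.root)


def _iter_chance_nodes(node: Node) -> Iterator[ChanceNode]:
    if isinstance(node, ChanceNode):
        yield node
        for branch in node.branches:
            yield from _iter_chance_nodes(branch.child)


def validate_tree(tree: DecisionTree, tolerance: float = 1e-9) -> ValidationReport:
    """Check that every chance node's branch probabilities sum to 1.

    Structural defects (cycles, childless chance nodes) raise
    :class:`TreeStructureError`; probability-sum deviations beyond
    ``tolerance`` are collected in the returned report.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    _check_structure(tree)
    violations = []
    for node in _iter_chance_nodes(tree.root):
        total = node.probability_sum()
        if abs(total - 1.0) > tolerance:
            violations.append((node.name, total, tolerance))
    return ValidationReport(valid=not violations, violations=violations)


def enumerate_pathways(tree: DecisionTree) -> list[Pathway]:
    """List every root-to-terminal pathway with its joint probability.

    The joint probability is the product of conditional probabilities along
    the route; one pathway is emitted per terminal, in branch order.
    """
    _check_structure(tree)
    pathways: list[Pathway] = []

    def walk(node: Node, labels: tuple[str, ...], prob: float) -> None:
        if isinstance(node, TerminalNode):
            pathways.append(Pathway(labels, prob, node))
            return
        for branch in node.branches:
            walk(branch.child, labels + (branch.label,), prob * branch.probability)

    walk(tree.root, (), 1.0)
    return pathways


def pathway_probability(conditionals) -> float:
    """Joint probability of one pathway from its conditional probabilities.

    The product rule: P(pathway) = prod of the conditional branch
    probabilities along the route.  An empty sequence is an error (there is
    no degenerate pathway).
    """
    conditionals = list(conditionals)
    if not conditionals:
        raise ValueError("pathway must have at least one branch")
    for p in conditionals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"conditional probability {p} not in [0, 1]")
    return math.prod(conditionals)


_PAYOFFS: dict[str, Callable[[TerminalNode], float]] = {
    "cost": lambda t: t.total_cost,
    "effect": lambda t: t.effect,
}


def expected_value(tree: DecisionTree, payoff: str = "cost") -> float:
    """Expected payoff of the tree, by leaf-to-root rollback.

    ``payoff`` selects the terminal attribute: ``"cost"`` or ``"effect"``.
    Rollback and pathway-enumeration summation agree to floating round-off;
    rollback is used because it is exact for the same arithmetic at lower
    cost on deep trees.
    """
    try:
        get = _PAYOFFS[payoff]
    except KeyError:
        raise ValueError(f"unknown payoff selector {payoff!r}; use 'cost' or 'effect'")
    _check_structure(tree)

    def roll(node: Node) -> float:
        if isinstance(node, TerminalNode):
            return get(node)
        return math.fsum(b.probability * roll(b.child) for b in node.branches)

    return roll(tree.root)
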