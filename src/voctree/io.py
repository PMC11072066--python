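"""Reading and writing tree definitions as structured config files.

Trees are stored in a flat node table: chance nodes keyed by name with
``(label, probability, child)`` branch triples, terminals keyed by name with
``(cost, effect)``.  YAML and JSON dialects are supported, chosen by file
extension.  Floats are written with full repr precision so a write-then-read
round trip reproduces every number bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .tree import Branch, ChanceNode, DecisionTree, TerminalNode, TreeStructureError

__all__ = ["tree_to_dict", "tree_from_dict", "save_tree", "load_tree"]

SCHEMA_VERSION = 1


def tree_to_dict(tree: DecisionTree) -> dict:
    """Serialize a tree to the flat node-table dict form."""
    nodes: dict[str, dict] = {}
    terminals: dict[str, dict] = {}

    def visit(node) -> str:
        if isinstance(node, TerminalNode):
            if node.name in terminals or node.name in nodes:
                raise ValueError(f"duplicate node name {node.name!r} in tree")
            terminals[node.name] = {"cost": node.total_cost, "effect": int(node.effect)}
            return node.name
        if node.name in nodes or node.name in terminals:
            raise ValueError(f"duplicate node name {node.name!r} in tree")
        entry: dict = {"branches": []}
        nodes[node.name] = entry
        for b in node.branches:
            entry["branches"].append(
                {"label": b.label, "probability": b.probability, "child": visit(b.child)}
            )
        return node.name

    root_name = visit(tree.root)
    return {
        "schema_version": SCHEMA_VERSION,
        "tree": {
            "name": tree.name,
            "root": root_name,
            "nodes": nodes,
            "terminals": terminals,
        },
    }


def tree_from_dict(data: dict) -> DecisionTree:
    """Rebuild a tree from its dict form; unknown node references are errors."""
    try:
        spec = data["tree"]
        nodes = spec["nodes"]
        terminals = spec["terminals"]
        root_name = spec["root"]
        name = spec["name"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed tree config: missing key {exc}") from exc

    building: set[str] = set()

    def build(node_name: str):
        if node_name in terminals:
            t = terminals[node_name]
            return TerminalNode(node_name, float(t["cost"]), float(t["effect"]))
        if node_name not in nodes:
            raise ValueError(f"unknown node reference {node_name!r}")
        if node_name in building:
            raise TreeStructureError(f"cycle detected at node {node_name!r}")
        building.add(node_name)
        branches = [
            Branch(b["label"], float(b["probability"]), build(b["child"]))
            for b in nodes[node_name]["branches"]
        ]
        building.discard(node_name)
        return ChanceNode(node_name, branches)

    return DecisionTree(name, build(root_name))


def save_tree(tree: DecisionTree, path: str | Path) -> None:
    """Write a tree config; dialect chosen by extension (.yaml/.yml or .json)."""
    path = Path(path)
    data = tree_to_dict(tree)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_tree(path: str | Path) -> DecisionTree:
    """Read a tree config written by :func:`save_tree`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return tree_from_dict(data)
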