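"""Indicator hierarchy and rating scale.

The evaluation object is a rooted three-level tree: one goal node (level 1),
a layer of criteria / "second-level" indicators (level 2), and the leaf
"third-level" indicators (level 3) that experts actually rate.  Weights are
attached per node and interpreted *within a sibling group*: whenever a group
weight vector is requested it is renormalized to sum to one, so globally
scaled weights (as published weight tables usually are) and locally
normalized ones are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import HierarchyError

__all__ = [
    "RatingScale",
    "IndicatorNode",
    "IndicatorHierarchy",
    "load_hierarchy",
    "write_hierarchy",
]

DEFAULT_GRADE_LABELS = (
    "very unimportant",
    "unimportant",
    "average",
    "important",
    "very important",
)


@dataclass(frozen=True)
class RatingScale:
    """Ordered evaluation grades and their numeric values.

    The default is the five-point Likert importance scale with values
    1..5 ascending (grade columns are always stored lowest grade first).
    """

    labels: tuple[str, ...] = DEFAULT_GRADE_LABELS
    values: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise HierarchyError(
                f"scale has {len(self.labels)} labels but {len(self.values)} values"
            )
        if len(self.values) < 2:
            raise HierarchyError("scale needs at least two grades")
        diffs = [b - a for a, b in zip(self.values, self.values[1:])]
        if not all(d > 0 for d in diffs):
            raise HierarchyError(f"scale values must be strictly increasing: {self.values}")

    @property
    def n_grades(self) -> int:
        return len(self.values)

    @property
    def min_value(self) -> float:
        return self.values[0]

    @property
    def max_value(self) -> float:
        return self.values[-1]

    def is_valid_grade(self, value: float) -> bool:
        return any(value == v for v in self.values)

    def normalize_score(self, score: float) -> float:
        """Map a score from [min_value, max_value] to [0, 1]."""
        return (score - self.min_value) / (self.max_value - self.min_value)

    def bracket(self, score: float) -> tuple[str, ...]:
        """Return the scale label(s) bracketing ``score``.

        An exact grade value returns a single label; anything in between
        returns ``(lower_label, upper_label)``.
        """
        if not (self.min_value <= score <= self.max_value):
            raise HierarchyError(
                f"score {score} outside scale range [{self.min_value}, {self.max_value}]"
            )
        for i, v in enumerate(self.values):
            if score == v:
                return (self.labels[i],)
        for i in range(len(self.values) - 1):
            if self.values[i] < score < self.values[i + 1]:
                return (self.labels[i], self.labels[i + 1])
        raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class IndicatorNode:
    """One node of the indicator tree."""

    id: str
    label: str = ""
    level: int = 3
    parent_id: str | None = None
    weight: float | None = None
    direction: str = "positive"  # orientation for entropy weighting of raw values

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise HierarchyError(f"node {self.id!r}: level must be 1, 2 or 3, got {self.level}")
        if self.weight is not None and self.weight < 0:
            raise HierarchyError(f"node {self.id!r}: negative weight {self.weight}")
        if self.direction not in ("positive", "negative"):
            raise HierarchyError(
                f"node {self.id!r}: direction must be 'positive' or 'negative'"
            )
        if self.parent_id == self.id:
            raise HierarchyError(f"node {self.id!r}: orphan/cycle — node is its own parent")


class IndicatorHierarchy:
    """A validated rooted tree of indicator nodes plus the rating scale."""

    def __init__(self, nodes: Iterable[IndicatorNode], scale: RatingScale | None = None):
        nodes = list(nodes)
        ids = [n.id for n in nodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise HierarchyError(f"duplicate node id(s): {sorted(dupes)}")
        self._nodes: dict[str, IndicatorNode] = {n.id: n for n in nodes}
        self.scale = scale or RatingScale()
        self._validate_tree()

    def _validate_tree(self) -> None:
        roots = [n for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        if root.level != 1:
            raise HierarchyError(f"root {root.id!r} must be level 1, got {root.level}")
        for n in self._nodes.values():
            if n.parent_id is None:
                continue
            parent = self._nodes.get(n.parent_id)
            if parent is None:
                raise HierarchyError(f"node {n.id!r}: unknown parent {n.parent_id!r}")
            if parent.level != n.level - 1:
                raise HierarchyError(
                    f"node {n.id!r} (level {n.level}): parent {parent.id!r} is level "
                    f"{parent.level}, expected {n.level - 1}"
                )
        for n in self._nodes.values():
            if n.level == 2 and not self.children(n.id):
                raise HierarchyError(f"level-2 node {n.id!r} has no children")

    # -- structure accessors -------------------------------------------------

    @property
    def nodes(self) -> dict[str, IndicatorNode]:
        return dict(self._nodes)

    @property
    def root(self) -> IndicatorNode:
        return next(n for n in self._nodes.values() if n.parent_id is None)

    @property
    def criteria(self) -> list[IndicatorNode]:
        """Level-2 nodes, in insertion order."""
        return [n for n in self._nodes.values() if n.level == 2]

    @property
    def leaves(self) -> list[IndicatorNode]:
        """Level-3 nodes, in insertion order."""
        return [n for n in self._nodes.values() if n.level == 3]

    @property
    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves]

    def __getitem__(self, node_id: str) -> IndicatorNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise HierarchyError(f"unknown node {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def children(self, node_id: str) -> list[IndicatorNode]:
        return [n for n in self._nodes.values() if n.parent_id == node_id]

    # -- weights -------------------------------------------------------------

    def group_weights(self, parent_id: str) -> "WeightVector":
        """Normalized weight vector over the children of ``parent_id``.

        Raises if any child lacks a weight.
        """
        from .weighting import WeightVector  # local import to avoid cycle

        kids = self.children(parent_id)
        if not kids:
            raise HierarchyError(f"node {parent_id!r} has no children")
        missing = [k.id for k in kids if k.weight is None]
        if missing:
            raise HierarchyError(f"children of {parent_id!r} missing weights: {missing}")
        return WeightVector({k.id: float(k.weight) for k in kids}).normalized()

    def set_weights(self, weights: Mapping[str, float]) -> None:
        for node_id, w in weights.items():
            self[node_id].weight = float(w)


def _node_from_mapping(raw: Mapping, index: int) -> IndicatorNode:
    if not isinstance(raw, Mapping) or "id" not in raw:
        raise HierarchyError(f"node entry #{index} is malformed (needs at least 'id'): {raw!r}")
    known = {"id", "label", "level", "parent", "weight", "direction"}
    unknown = set(raw) - known
    if unknown:
        raise HierarchyError(f"node {raw['id']!r}: unknown key(s) {sorted(unknown)}")
    try:
        return IndicatorNode(
            id=str(raw["id"]),
            label=str(raw.get("label", "")),
            level=int(raw.get("level", 3)),
            parent_id=(None if raw.get("parent") is None else str(raw["parent"])),
            weight=(None if raw.get("weight") is None else float(raw["weight"])),
            direction=str(raw.get("direction", "positive")),
        )
    except (TypeError, ValueError) as exc:
        raise HierarchyError(f"node {raw.get('id')!r}: {exc}") from exc


def load_hierarchy(path: str | Path) -> IndicatorHierarchy:
    """Load an indicator hierarchy from a YAML config file.

    Schema::

        scale:              # optional; default 5-grade Likert, values 1..5
          labels: [...]
          values: [...]
        nodes:
          - {id: A,  label: goal,      level: 1}
          - {id: A1, label: criterion, level: 2, parent: A, weight: 0.4}
          - {id: G1, label: leaf,      level: 3, parent: A1, weight: 0.1,
             direction: positive}
    """
    path = Path(path)
    if not path.exists():
        raise HierarchyError(f"hierarchy file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise HierarchyError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, Mapping) or "nodes" not in doc:
        raise HierarchyError(f"{path}: top level must be a mapping with a 'nodes' list")
    scale = RatingScale()
    if "scale" in doc and doc["scale"] is not None:
        s = doc["scale"]
        scale = RatingScale(
            labels=tuple(str(x) for x in s.get("labels", DEFAULT_GRADE_LABELS)),
            values=tuple(float(x) for x in s.get("values", (1, 2, 3, 4, 5))),
        )
    nodes = [_node_from_mapping(raw, i) for i, raw in enumerate(doc["nodes"])]
    return IndicatorHierarchy(nodes, scale=scale)


def write_hierarchy(hierarchy: IndicatorHierarchy, path: str | Path) -> None:
    """Write a hierarchy back to the YAML config format (round-trips exactly)."""
    doc: dict = {
        "scale": {
            "labels": list(hierarchy.scale.labels),
            "values": [float(v) for v in hierarchy.scale.values],
        },
        "nodes": [],
    }
    for n in hierarchy.nodes.values():
        entry: dict = {"id": n.id, "label": n.label, "level": n.level}
        if n.parent_id is not None:
            entry["parent"] = n.parent_id
        if n.weight is not None:
            entry["weight"] = float(n.weight)
        if n.direction != "positive":
            entry["direction"] = n.direction
        doc["nodes"].append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
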