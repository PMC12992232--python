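"""Fuzzy comprehensive evaluation (FCE).

The FCE chain is: expert ratings -> per-indicator grade-membership rows
(matrix R, each row the fraction of respondents assigning each grade) ->
weighted synthesis A = W . R over each sibling group -> defuzzified score
P = A . V against the grade values -> grade/band assignment.

The synthesis operator is the weighted-average (., +) matrix product, which
is what the P = W.R.V formulation denotes; the classical max–min
composition is available behind ``operator="max_min"`` for comparison but
does not conserve mass and is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .hierarchy import IndicatorHierarchy, RatingScale
from .panel import ExpertPanel
from .weighting import WeightVector

__all__ = [
    "MembershipMatrix",
    "EvaluationVector",
    "CompositeScore",
    "GradeScheme",
    "GradeAssignment",
    "membership_matrix",
    "synthesize",
    "defuzzify",
    "aggregate_hierarchy",
    "aggregate_fixed_scores",
    "assign_grade",
]

# Performance bands on the normalized [0, 1] axis, lower-inclusive except the
# top band which is closed at 1.0.
DEFAULT_BANDS = (
    ("poor", 0.0, 0.2),
    ("average", 0.2, 0.4),
    ("medium", 0.4, 0.6),
    ("good", 0.6, 0.8),
    ("excellent", 0.8, 1.0),
)


@dataclass
class MembershipMatrix:
    """Grade-membership rows per leaf indicator (the fuzzy matrix R).

    ``rows`` is a DataFrame indexed by leaf id with one column per grade,
    lowest grade first; every row sums to 1.  ``counts`` records how many
    respondents each row was estimated from.
    """

    rows: pd.DataFrame
    counts: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.rows.to_numpy(dtype=float)
        if np.any(arr < -1e-12):
            raise EvaluationError("membership degrees must be nonnegative")
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            leaf = self.rows.index[int(np.argmax(bad))]
            raise EvaluationError(
                f"membership row {leaf!r} sums to {sums[np.argmax(bad)]:.8f}, expected 1"
            )

    @property
    def leaf_ids(self) -> list[str]:
        return list(self.rows.index)

    def row(self, leaf_id: str) -> np.ndarray:
        if leaf_id not in self.rows.index:
            raise EvaluationError(f"no membership row for leaf {leaf_id!r}")
        return self.rows.loc[leaf_id].to_numpy(dtype=float)

    def subset(self, leaf_ids: list[str]) -> "MembershipMatrix":
        missing = [l for l in leaf_ids if l not in self.rows.index]
        if missing:
            raise EvaluationError(f"no membership row for leaf/leaves {missing}")
        counts = self.counts.loc[leaf_ids] if self.counts is not None else None
        return MembershipMatrix(self.rows.loc[leaf_ids], counts)


@dataclass
class EvaluationVector:
    """A grade-membership distribution for one (possibly aggregated) node."""

    grades: tuple[str, ...]
    degrees: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=float)
        if len(d) != len(self.grades):
            raise EvaluationError(
                f"{len(d)} degrees for {len(self.grades)} grades"
            )
        if np.any(d < -1e-12):
            raise EvaluationError("membership degrees must be nonnegative")
        if abs(d.sum() - 1.0) > 1e-6:
            raise EvaluationError(f"evaluation vector sums to {d.sum():.8f}, expected 1")
        self.degrees = d


@dataclass
class CompositeScore:
    """Defuzzified score for one node, with its evaluation vector."""

    node_id: str
    score: float
    vector: EvaluationVector | None
    grade_label: str
    normalized: float


@dataclass(frozen=True)
class GradeScheme:
    """Ordered performance bands partitioning the normalized [0, 1] axis."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        lo = 0.0
        for label, a, b in self.bands:
            if a != lo or b <= a:
                raise EvaluationError(f"bands must partition [0,1]; bad band {label!r}")
            lo = b
        if lo != 1.0:
            raise EvaluationError("bands must end at 1.0")

    def band(self, normalized: float) -> str:
        if not (0.0 <= normalized <= 1.0):
            raise EvaluationError(f"normalized score {normalized} outside [0, 1]")
        for label, a, b in self.bands:
            if a <= normalized < b:
                return label
        return self.bands[-1][0]  # normalized == 1.0, top band upper-closed

    def describe(self) -> list[str]:
        return [f"{label} ({b:.1f}–{a:.1f})" for label, a, b in self.bands]


@dataclass
class GradeAssignment:
    """Band on the normalized axis plus the bracketing scale labels."""

    band: str
    bracket: tuple[str, ...]


def membership_matrix(
    panel: ExpertPanel, hierarchy: IndicatorHierarchy
) -> MembershipMatrix:
    """Estimate R from an expert panel by per-grade response frequencies.

    r[leaf][grade] = (# experts giving that grade) / (# non-missing
    responses for that leaf).  Missing cells are simply excluded from the
    denominator, so indicators answered by different respondent subsets are
    handled uniformly.
    """
    panel.validate(hierarchy)
    scale = hierarchy.scale
    leaf_ids = [l for l in hierarchy.leaf_ids if l in panel.ratings.columns]
    missing = [l for l in hierarchy.leaf_ids if l not in panel.ratings.columns]
    if missing:
        raise EvaluationError(f"panel has no column for leaf/leaves {missing}")
    rows = pd.DataFrame(0.0, index=leaf_ids, columns=list(scale.labels))
    counts = pd.Series(0, index=leaf_ids, dtype=int, name="n_respondents")
    for leaf in leaf_ids:
        col = panel.ratings[leaf].dropna()
        if len(col) == 0:
            raise EvaluationError(f"leaf {leaf!r} has zero responses")
        counts[leaf] = len(col)
        for label, value in zip(scale.labels, scale.values):
            rows.loc[leaf, label] = float((col == value).sum()) / len(col)
    return MembershipMatrix(rows=rows, counts=counts)


def synthesize(
    W: WeightVector, R: MembershipMatrix, *, operator: str = "weighted_average"
) -> EvaluationVector:
    """Fuzzy synthesis A = W . R over one sibling group.

    The weight keys must match R's rows exactly (order taken from W).
    """
    missing = [k for k in W.keys if k not in R.rows.index]
    if missing or len(W) != len(R.rows):
        raise EvaluationError(
            f"weight keys {sorted(W.keys)} do not match membership rows "
            f"{sorted(R.rows.index)}"
        )
    if abs(W.values.sum() - 1.0) > 1e-9:
        raise EvaluationError("weight vector is not normalized")
    mat = R.rows.loc[list(W.keys)].to_numpy(dtype=float)
    if operator == "weighted_average":
        degrees = W.values @ mat
    elif operator == "max_min":
        degrees = np.max(np.minimum(W.values[:, None], mat), axis=0)
        total = degrees.sum()
        if total <= 0:
            raise EvaluationError("max-min composition produced an all-zero vector")
        degrees = degrees / total  # renormalized so the vector is a distribution
    else:
        raise EvaluationError(f"unknown operator {operator!r}")
    return EvaluationVector(grades=tuple(R.rows.columns), degrees=degrees)


def defuzzify(A: EvaluationVector, scale: RatingScale) -> float:
    """Collapse an evaluation vector to its expected grade value P = A . V."""
    if len(A.degrees) != scale.n_grades:
        raise EvaluationError(
            f"vector has {len(A.degrees)} grades, scale has {scale.n_grades}"
        )
    return float(np.dot(A.degrees, np.asarray(scale.values)))


def _composite(
    node_id: str,
    vector: EvaluationVector | None,
    score: float,
    scale: RatingScale,
    scheme: GradeScheme,
) -> CompositeScore:
    normalized = scale.normalize_score(score)
    return CompositeScore(
        node_id=node_id,
        score=score,
        vector=vector,
        grade_label=scheme.band(normalized),
        normalized=normalized,
    )


def aggregate_hierarchy(
    hierarchy: IndicatorHierarchy,
    R: MembershipMatrix,
    weights: Mapping[str, WeightVector] | None = None,
    *,
    scheme: GradeScheme | None = None,
) -> dict[str, CompositeScore]:
    """Bottom-up aggregation of the full tree.

    ``weights`` maps each parent node id to the normalized weight vector
    over its children; when omitted, the weights stored on the hierarchy
    nodes are used (renormalized within each sibling group).  Returns a
    CompositeScore for every node: leaves carry their own membership row,
    each level-2 node the synthesis of its children, the root the synthesis
    of the level-2 vectors.
    """
    scheme = scheme or GradeScheme()
    scale = hierarchy.scale
    root = hierarchy.root

    def group_w(parent_id: str) -> WeightVector:
        if weights is not None:
            if parent_id not in weights:
                raise EvaluationError(f"no weight vector for children of {parent_id!r}")
            return weights[parent_id].normalized()
        return hierarchy.group_weights(parent_id)

    out: dict[str, CompositeScore] = {}
    for leaf in hierarchy.leaves:
        vec = EvaluationVector(grades=tuple(R.rows.columns), degrees=R.row(leaf.id))
        out[leaf.id] = _composite(leaf.id, vec, defuzzify(vec, scale), scale, scheme)

    level2_rows = {}
    for crit in hierarchy.criteria:
        w = group_w(crit.id).reorder([c.id for c in hierarchy.children(crit.id)])
        vec = synthesize(w, R.subset(list(w.keys)))
        out[crit.id] = _composite(crit.id, vec, defuzzify(vec, scale), scale, scheme)
        level2_rows[crit.id] = vec.degrees

    w_root = group_w(root.id).reorder([c.id for c in hierarchy.criteria])
    R2 = MembershipMatrix(
        rows=pd.DataFrame(
            np.vstack([level2_rows[k] for k in w_root.keys]),
            index=list(w_root.keys),
            columns=list(R.rows.columns),
        )
    )
    vec = synthesize(w_root, R2)
    out[root.id] = _composite(root.id, vec, defuzzify(vec, scale), scale, scheme)
    return out


def aggregate_fixed_scores(
    weights: WeightVector,
    scores: Mapping[str, float],
    scale: RatingScale | None = None,
    *,
    scheme: GradeScheme | None = None,
    node_id: str = "root",
) -> CompositeScore:
    """Weighted sum of fixed per-node scalar scores (reported-table mode).

    Used when the sub-scores are given directly (e.g. published dimension
    scores) rather than derived from a membership matrix; the composite is
    the normalized-weight average of the scores.
    """
    scale = scale or RatingScale()
    scheme = scheme or GradeScheme()
    missing = [k for k in weights.keys if k not in scores]
    if missing:
        raise EvaluationError(f"no score for node(s) {missing}")
    vals = np.asarray([scores[k] for k in weights.keys], dtype=float)
    if np.any(vals < scale.min_value) or np.any(vals > scale.max_value):
        raise EvaluationError(f"scores outside scale range: {dict(scores)}")
    w = weights.normalized()
    score = float(np.dot(w.values, vals))
    return _composite(node_id, None, score, scale, scheme)


def assign_grade(
    score: CompositeScore | float,
    scheme: GradeScheme | None = None,
    scale: RatingScale | None = None,
) -> GradeAssignment:
    """Band on the normalized [0, 1] axis plus bracketing scale labels.

    A raw float is accepted in place of a CompositeScore.  Exact grade
    values yield a single bracketing label.
    """
    scheme = scheme or GradeScheme()
    scale = scale or RatingScale()
    raw = score.score if isinstance(score, CompositeScore) else float(score)
    return GradeAssignment(
        band=scheme.band(scale.normalize_score(raw)),
        bracket=scale.bracket(raw),
    )
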