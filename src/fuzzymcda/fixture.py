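"""Bundled Jilin Province food-safety governance case study.

A complete worked example shipped with the package: the 4 + 18 indicator
hierarchy with its published weights, the government-regulatory-capacity
(G) block of the fuzzy membership matrix, the published per-dimension
synthesis scores, and the 33-expert roster.  Values are stored verbatim at
their published precision and serve as the reference fixture for tests and
the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .hierarchy import IndicatorHierarchy, load_hierarchy
from .panel import ExpertProfile

__all__ = ["CaseBundle", "jilin_case", "data_path"]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("fuzzymcda").joinpath("data", name))  # type: ignore[arg-type]


@dataclass
class CaseBundle:
    """The Jilin case: hierarchy, weights, partial R, dimension scores, experts."""

    hierarchy: IndicatorHierarchy
    criteria_weights: dict[str, float]  # level-2 global weights (A1..A4)
    leaf_weights: dict[str, float]  # level-3 global weights (18 leaves)
    membership: pd.DataFrame  # G-block rows of R, grades ascending
    dimension_scores: dict[str, float]  # published per-dimension synthesis scores
    dimension_descriptions: dict[str, str]
    experts: list[ExpertProfile]


def jilin_case() -> CaseBundle:
    """Load the bundled case study at published precision."""
    hierarchy = load_hierarchy(data_path("jilin_hierarchy.yaml"))
    criteria_weights = {n.id: float(n.weight) for n in hierarchy.criteria}
    leaf_weights = {n.id: float(n.weight) for n in hierarchy.leaves}

    membership = pd.read_csv(data_path("jilin_g_membership.csv"), index_col="leaf")
    membership.columns = list(hierarchy.scale.labels)

    dims = pd.read_csv(data_path("jilin_dimension_scores.csv"), index_col="node")
    experts_df = pd.read_csv(data_path("jilin_experts.csv"))
    experts = [
        ExpertProfile(
            person_id=str(r.person),
            workplace=str(r.workplace),
            education=str(r.education),
            experience_years=int(r.experience),
            sex=str(r.sex),
        )
        for r in experts_df.itertuples()
    ]
    return CaseBundle(
        hierarchy=hierarchy,
        criteria_weights=criteria_weights,
        leaf_weights=leaf_weights,
        membership=membership,
        dimension_scores={k: float(v) for k, v in dims["score"].items()},
        dimension_descriptions={k: str(v) for k, v in dims["description"].items()},
        experts=experts,
    )
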