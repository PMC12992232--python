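"""Synthetic expert panels and raw indicator matrices.

The panel generator draws each expert's rating of each leaf indicator
i.i.d. from that leaf's *consensus distribution* — a probability vector
over the five grades.  This is exactly the object the membership-matrix
stage estimates, so parameter recovery (generated panel -> R -> consensus)
is a clean end-to-end check.  Response thinning (a cell is answered with
probability ``response_rate``) emulates indicators rated by only a subset
of the panel.

The raw-matrix generator draws log-normal columns, exp(dispersion * z)
with z standard normal: dispersion 0 gives a constant column and larger
dispersion gives more skewed (more informative) columns, so entropy
weights increase with dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FuzzymcdaError
from .fixture import jilin_case
from .panel import ExpertPanel, ExpertProfile
from .weighting import RawIndicatorMatrix

__all__ = [
    "PanelSpec",
    "RawMatrixSpec",
    "generate_panel",
    "generate_raw_matrix",
    "jilin_panel_spec",
]

# Default workplace mix: 15 regulators (GRA), 8 producers (FPE), 6 testing
# institutions (TTI), 4 consumer organizations (CO).
DEFAULT_STRATA = {"GRA": 15, "FPE": 8, "TTI": 6, "CO": 4}


@dataclass
class PanelSpec:
    """Specification of a synthetic expert panel."""

    n_experts: int
    leaves: tuple[str, ...]
    consensus: dict[str, tuple[float, ...]]  # per-leaf probability over grades
    response_rate: dict[str, float] = field(default_factory=dict)  # default 1.0
    strata: dict[str, int] | None = None  # workplace -> count; None = no profiles
    grade_values: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise FuzzymcdaError(f"n_experts must be >= 1, got {self.n_experts}")
        for leaf in self.leaves:
            if leaf not in self.consensus:
                raise FuzzymcdaError(f"no consensus vector for leaf {leaf!r}")
            p = np.asarray(self.consensus[leaf], dtype=float)
            if len(p) != len(self.grade_values):
                raise FuzzymcdaError(
                    f"consensus for {leaf!r} has {len(p)} entries, expected "
                    f"{len(self.grade_values)}"
                )
            # printed-precision rows may be off by ~1e-6; renormalized on draw
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-5:
                raise FuzzymcdaError(f"consensus for {leaf!r} is not a distribution: {p}")
            r = self.response_rate.get(leaf, 1.0)
            if not (0.0 < r <= 1.0):
                raise FuzzymcdaError(f"response_rate for {leaf!r} must be in (0, 1]: {r}")
        if self.strata is not None and sum(self.strata.values()) != self.n_experts:
            raise FuzzymcdaError(
                f"strata counts sum to {sum(self.strata.values())}, "
                f"expected n_experts={self.n_experts}"
            )


@dataclass
class RawMatrixSpec:
    """Specification of a synthetic raw indicator matrix."""

    n_items: int
    indicators: tuple[str, ...]
    dispersion: dict[str, float] = field(default_factory=dict)  # default 1.0
    directions: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise FuzzymcdaError(f"n_items must be >= 2, got {self.n_items}")
        for ind, d in self.dispersion.items():
            if ind not in self.indicators:
                raise FuzzymcdaError(f"dispersion for unknown indicator {ind!r}")
            if d < 0:
                raise FuzzymcdaError(f"dispersion for {ind!r} must be >= 0: {d}")


def generate_panel(spec: PanelSpec, *, max_retries: int = 100) -> ExpertPanel:
    """Draw a synthetic panel from the spec, deterministically under its seed."""
    rng = np.random.default_rng(spec.seed)
    values = np.asarray(spec.grade_values)
    ratings = pd.DataFrame(
        index=[f"S{i + 1}" for i in range(spec.n_experts)],
        columns=list(spec.leaves),
        dtype=float,
    )
    for leaf in spec.leaves:
        p = np.asarray(spec.consensus[leaf], dtype=float)
        r = spec.response_rate.get(leaf, 1.0)
        for attempt in range(max_retries):
            grades = rng.choice(values, size=spec.n_experts, p=p / p.sum())
            answered = rng.random(spec.n_experts) < r
            if answered.any():
                break
        else:
            raise FuzzymcdaError(
                f"leaf {leaf!r}: no respondents after {max_retries} thinning draws"
            )
        col = np.where(answered, grades, np.nan)
        ratings[leaf] = col

    profiles = None
    if spec.strata is not None:
        workplaces = [w for w, c in spec.strata.items() for _ in range(c)]
        rng.shuffle(workplaces)
        profiles = [
            ExpertProfile(person_id=pid, workplace=w)
            for pid, w in zip(ratings.index, workplaces)
        ]
    return ExpertPanel(ratings, profiles)


def generate_raw_matrix(spec: RawMatrixSpec) -> RawIndicatorMatrix:
    """Draw a synthetic raw matrix; column skew grows with dispersion."""
    rng = np.random.default_rng(spec.seed)
    data = {}
    for ind in spec.indicators:
        d = spec.dispersion.get(ind, 1.0)
        data[ind] = np.exp(d * rng.standard_normal(spec.n_items))
    return RawIndicatorMatrix(
        values=pd.DataFrame(data), directions=dict(spec.directions)
    )


# Consensus defaults for the non-G blocks of the bundled case spec, chosen so
# each block's expected score matches its published dimension score: the E
# block centres on grade 3, the T and C blocks midway between 3 and 4.
_E_CONSENSUS = (0.05, 0.20, 0.50, 0.20, 0.05)  # mean 3.0
_TC_CONSENSUS = (0.0, 0.05, 0.40, 0.45, 0.10)  # mean 3.6


def jilin_panel_spec(seed: int = 0) -> PanelSpec:
    """Panel spec mirroring the bundled case study conditions.

    33 experts stratified 15/8/6/4 over GRA/FPE/TTI/CO; the G-block
    consensus vectors are the bundled membership rows with per-leaf
    response rate 17/33 (those rows were estimated from 17 respondents);
    the other blocks use block-level consensus defaults whose expected
    scores match the published dimension scores.
    """
    case = jilin_case()
    leaves = tuple(case.hierarchy.leaf_ids)
    consensus: dict[str, tuple[float, ...]] = {}
    response_rate: dict[str, float] = {}
    for leaf in leaves:
        if leaf.startswith("G"):
            consensus[leaf] = tuple(case.membership.loc[leaf].to_numpy(dtype=float))
            response_rate[leaf] = 17 / 33
        elif leaf.startswith("E"):
            consensus[leaf] = _E_CONSENSUS
        else:
            consensus[leaf] = _TC_CONSENSUS
    return PanelSpec(
        n_experts=33,
        leaves=leaves,
        consensus=consensus,
        response_rate=response_rate,
        strata=dict(DEFAULT_STRATA),
        seed=seed,
    )
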