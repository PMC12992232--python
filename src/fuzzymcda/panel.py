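"""Expert panel: the ratings table and optional respondent profiles.

Ratings live in a pandas DataFrame with one row per expert and one column
per leaf indicator; cells hold integer grade values of the rating scale, or
NaN for a missing response.  Missing cells are first-class: a respondent may
rate only the indicators they answered, and every membership degree is
computed over the non-missing responses of that indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PanelError
from .hierarchy import IndicatorHierarchy

__all__ = ["ExpertProfile", "ExpertPanel", "load_panel", "write_panel"]

WORKPLACE_CATEGORIES = ("GRA", "FPE", "TTI", "CO")
PROFILE_COLUMNS = ("workplace", "education", "experience", "sex")


@dataclass(frozen=True)
class ExpertProfile:
    """Respondent metadata (workplace category, education, experience, sex)."""

    person_id: str
    workplace: str | None = None
    education: str | None = None
    experience_years: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.workplace is not None and self.workplace not in WORKPLACE_CATEGORIES:
            raise PanelError(
                f"expert {self.person_id!r}: workplace {self.workplace!r} not in "
                f"{WORKPLACE_CATEGORIES}"
            )
        if self.experience_years is not None and self.experience_years < 0:
            raise PanelError(
                f"expert {self.person_id!r}: negative experience {self.experience_years}"
            )


class ExpertPanel:
    """Ratings matrix (experts x leaf indicators) plus optional profiles."""

    def __init__(
        self,
        ratings: pd.DataFrame,
        profiles: list[ExpertProfile] | None = None,
    ):
        self.ratings = ratings.astype(float)
        self.profiles = profiles
        if profiles is not None and len(profiles) != len(ratings):
            raise PanelError(
                f"{len(profiles)} profiles for {len(ratings)} rating rows"
            )

    @property
    def n_experts(self) -> int:
        return len(self.ratings)

    @property
    def leaf_ids(self) -> list[str]:
        return list(self.ratings.columns)

    def response_counts(self) -> pd.Series:
        """Non-missing responses per leaf indicator."""
        return self.ratings.notna().sum(axis=0)

    def validate(self, hierarchy: IndicatorHierarchy) -> None:
        """Check alignment with the hierarchy leaves and the grade codes."""
        leaf_ids = set(hierarchy.leaf_ids)
        unknown = [c for c in self.ratings.columns if c not in leaf_ids]
        if unknown:
            kinds = [
                "non-leaf node" if c in hierarchy else "unknown indicator"
                for c in unknown
            ]
            raise PanelError(
                f"rating column(s) not hierarchy leaves: "
                f"{[f'{c} ({k})' for c, k in zip(unknown, kinds)]}"
            )
        scale = hierarchy.scale
        arr = self.ratings.to_numpy()
        bad = ~np.isnan(arr) & ~np.isin(arr, np.asarray(scale.values))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"rating {arr[i, j]:g} at row {self.ratings.index[i]!r}, column "
                f"{self.ratings.columns[j]!r} is not a grade value of the scale "
                f"{scale.values}"
            )
        empty = [c for c in self.ratings.columns if self.ratings[c].notna().sum() == 0]
        if empty:
            raise PanelError(f"leaf indicator(s) with zero responses: {empty}")

    def subset(self, expert_index: "np.ndarray | list[int]") -> "ExpertPanel":
        """Panel restricted to the given expert row positions."""
        ratings = self.ratings.iloc[list(expert_index)]
        profiles = (
            [self.profiles[i] for i in expert_index] if self.profiles is not None else None
        )
        return ExpertPanel(ratings, profiles)


def load_panel(path: str | Path, hierarchy: IndicatorHierarchy) -> ExpertPanel:
    """Load a panel CSV and validate it against the hierarchy.

    The header names leaf indicator ids; an optional leading ``person``
    column and optional ``workplace``/``education``/``experience``/``sex``
    columns carry profiles.  Empty cells are missing responses.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"person": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise PanelError(f"cannot parse {path}: {exc}") from exc

    if "person" in df.columns:
        df = df.set_index("person")
    else:
        df.index = [f"P{i + 1}" for i in range(len(df))]

    profile_cols = [c for c in PROFILE_COLUMNS if c in df.columns]
    profiles = None
    if profile_cols:
        profiles = []
        for pid, row in df[profile_cols].iterrows():
            profiles.append(
                ExpertProfile(
                    person_id=str(pid),
                    workplace=_opt_str(row.get("workplace")),
                    education=_opt_str(row.get("education")),
                    experience_years=(
                        None
                        if "experience" not in row or pd.isna(row["experience"])
                        else int(row["experience"])
                    ),
                    sex=_opt_str(row.get("sex")),
                )
            )
        df = df.drop(columns=profile_cols)

    for col in df.columns:
        bad = df[col].apply(
            lambda v: not (pd.isna(v) or (isinstance(v, (int, float)) and float(v) == int(v)))
        )
        if bad.any():
            row = df.index[bad.argmax()]
            raise PanelError(f"non-integer rating at row {row!r}, column {col!r}")

    panel = ExpertPanel(df.astype(float), profiles)
    panel.validate(hierarchy)
    return panel


def write_panel(panel: ExpertPanel, path: str | Path) -> None:
    """Write a panel to CSV; round-trips through :func:`load_panel`."""
    out = panel.ratings.copy()
    out = out.astype("Int64")  # keeps integer grades while allowing missing cells
    out.insert(0, "person", out.index)
    if panel.profiles is not None:
        out["workplace"] = [p.workplace for p in panel.profiles]
        out["education"] = [p.education for p in panel.profiles]
        out["experience"] = pd.array(
            [p.experience_years for p in panel.profiles], dtype="Int64"
        )
        out["sex"] = [p.sex for p in panel.profiles]
    out.to_csv(path, index=False)


def _opt_str(v) -> str | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)
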