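"""Weight determination: entropy weight method and AHP.

Two routes produce a weight vector over a sibling group of indicators:

* **Entropy weights** (objective): min–max normalize a raw items x
  indicators matrix X to Y, form column proportions P, compute each
  column's information entropy E_j = -(1/ln n) * sum_i p_ij ln p_ij, and
  weight each indicator by its information content,
  W_j = (1 - E_j) / (k - sum E).  Dispersed indicators get larger weights.

* **AHP** (subjective): a positive reciprocal pairwise-comparison matrix on
  the Saaty 1–9 scale, weights from the principal eigenvector, with the
  standard consistency test CR = CI / RI, CI = (lambda_max - n)/(n - 1),
  accepted when CR < 0.1.

``combine_weights`` takes a convex combination of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import WeightError

__all__ = [
    "WeightVector",
    "RawIndicatorMatrix",
    "EntropyWeightResult",
    "PairwiseMatrix",
    "AhpResult",
    "minmax_normalize",
    "entropy_weights",
    "likert_to_pairwise",
    "principal_weights",
    "combine_weights",
    "SAATY_RI",
]

# Saaty random consistency indices by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

# Saaty intensities for absolute Likert mean differences 0..4.
_DIFF_TO_SAATY = {0: 1.0, 1: 3.0, 2: 5.0, 3: 7.0, 4: 9.0}


class WeightVector:
    """Nonnegative weights over named siblings, normalized to sum 1."""

    def __init__(self, weights: Mapping[str, float], *, normalize: bool = True):
        keys = list(weights)
        vals = np.asarray([weights[k] for k in keys], dtype=float)
        if len(keys) == 0:
            raise WeightError("empty weight vector")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise WeightError(f"weights must be finite and nonnegative: {dict(weights)}")
        total = vals.sum()
        if normalize:
            if total <= 0:
                raise WeightError("weights sum to zero; cannot normalize")
            vals = vals / total
        elif abs(total - 1.0) > 1e-9:
            raise WeightError(f"weights sum to {total}, expected 1")
        self._keys = tuple(keys)
        self._values = vals

    @property
    def keys(self) -> tuple[str, ...]:
        return self._keys

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    def __getitem__(self, key: str) -> float:
        try:
            return float(self._values[self._keys.index(key)])
        except ValueError:
            raise WeightError(f"unknown key {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __repr__(self) -> str:
        items = ", ".join(f"{k}: {v:.6f}" for k, v in self.items())
        return f"WeightVector({{{items}}})"

    def items(self):
        return zip(self._keys, self._values)

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(self._values, index=list(self._keys), name="weight")

    def normalized(self) -> "WeightVector":
        return WeightVector(self.as_dict(), normalize=True)

    def reorder(self, keys: list[str]) -> "WeightVector":
        if set(keys) != set(self._keys):
            raise WeightError(f"key mismatch: {sorted(keys)} vs {sorted(self._keys)}")
        return WeightVector({k: self[k] for k in keys}, normalize=False)


@dataclass
class RawIndicatorMatrix:
    """Raw items x indicators value matrix X for entropy weighting.

    ``directions`` flags each indicator as benefit ("positive", larger is
    better) or cost ("negative"); cost columns are mirrored during
    normalization.
    """

    values: pd.DataFrame
    directions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise WeightError("raw indicator matrix contains missing entries")
        if len(self.values) < 2:
            raise WeightError(f"need >= 2 items, got {len(self.values)}")
        dirs = dict(self.directions or {})
        unknown = set(dirs) - set(self.values.columns)
        if unknown:
            raise WeightError(f"direction(s) for unknown indicator(s): {sorted(unknown)}")
        bad = {k: v for k, v in dirs.items() if v not in ("positive", "negative")}
        if bad:
            raise WeightError(f"invalid direction(s): {bad}")
        self.directions = {c: dirs.get(c, "positive") for c in self.values.columns}

    @property
    def n_items(self) -> int:
        return len(self.values)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EntropyWeightResult:
    """All intermediate arrays of the entropy-weight computation."""

    normalized: pd.DataFrame  # Y, entries in [0, 1]
    proportions: pd.DataFrame  # P, columns sum to 1 (or 0 for an all-zero column)
    entropies: pd.Series  # E_j in [0, 1]
    weights: WeightVector  # W_j, sums to 1


def minmax_normalize(X: RawIndicatorMatrix) -> pd.DataFrame:
    """De-dimensionalize each indicator column to [0, 1].

    Benefit columns map via (x - min)/(max - min); cost columns via the
    mirror (max - x)/(max - min).  A constant column carries no information
    and is set to all 0.5 (its entropy is later forced to 1, so its weight
    is exactly zero); a warning is emitted.
    """
    Y = pd.DataFrame(index=X.values.index, columns=X.values.columns, dtype=float)
    for col in X.values.columns:
        x = X.values[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(
                f"indicator {col!r} is constant; normalized to 0.5 and given zero weight",
                stacklevel=2,
            )
            Y[col] = 0.5
        elif X.directions[col] == "positive":
            Y[col] = (x - lo) / (hi - lo)
        else:
            Y[col] = (hi - x) / (hi - lo)
    return Y


def entropy_weights(X: RawIndicatorMatrix) -> EntropyWeightResult:
    """Entropy-weight method over a raw indicator matrix.

    Uses the 0*ln(0) := 0 convention; a constant column gets entropy
    exactly 1 and weight 0.  Raises when *every* column has entropy 1
    (no indicator discriminates between items).
    """
    Y = minmax_normalize(X)
    n = X.n_items
    col_sums = Y.sum(axis=0)
    P = Y / col_sums.replace(0.0, np.nan)
    P = P.fillna(0.0)

    E = pd.Series(index=Y.columns, dtype=float, name="entropy")
    for col in Y.columns:
        p = P[col].to_numpy()
        x = X.values[col].to_numpy(dtype=float)
        if x.max() == x.min():
            E[col] = 1.0  # constant column: no information by convention
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        E[col] = -terms.sum() / np.log(n)

    k = len(Y.columns)
    denom = k - E.sum()
    if denom <= 0 or np.isclose(denom, 0.0):
        raise WeightError(
            "no discriminating information: every indicator has entropy 1"
        )
    W = (1.0 - E) / denom
    weights = WeightVector({c: float(W[c]) for c in Y.columns})
    return EntropyWeightResult(normalized=Y, proportions=P, entropies=E, weights=weights)


@dataclass
class PairwiseMatrix:
    """Positive reciprocal judgment matrix on the Saaty 1–9 scale."""

    entries: np.ndarray
    keys: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.entries, dtype=float)
        n = len(self.keys)
        if A.shape != (n, n):
            raise WeightError(f"matrix shape {A.shape} does not match {n} keys")
        if np.any(A <= 0):
            raise WeightError("judgment matrix entries must be positive")
        if np.any(A < 1 / 9 - 1e-9) or np.any(A > 9 + 1e-9):
            raise WeightError("judgment matrix entries must lie in [1/9, 9]")
        if not np.allclose(np.diag(A), 1.0, atol=1e-9):
            raise WeightError("judgment matrix diagonal must be 1")
        if not np.allclose(A * A.T, 1.0, atol=1e-9):
            raise WeightError("judgment matrix must be reciprocal (a_ij * a_ji = 1)")
        self.entries = A

    @property
    def n(self) -> int:
        return len(self.keys)


@dataclass
class AhpResult:
    """Principal-eigenvector weights plus the consistency diagnostics."""

    weights: WeightVector
    lambda_max: float
    ci: float
    cr: float
    consistent: bool


def likert_to_pairwise(mean_scores: Mapping[str, float]) -> PairwiseMatrix:
    """Build a judgment matrix from per-sibling mean Likert ratings.

    The mapping is d = round(mean_i - mean_j) clipped to [-4, 4];
    |d| of 0,1,2,3,4 maps to Saaty intensity 1,3,5,7,9, reciprocal for
    negative d.  Equal means give a_ij = 1.  The map is a documented
    convention (monotone, reciprocal by construction, spanning 1–9);
    alternatives can be swapped in by building a PairwiseMatrix directly.
    """
    keys = list(mean_scores)
    if not keys:
        raise WeightError("empty sibling group")
    means = np.asarray([mean_scores[k] for k in keys], dtype=float)
    if np.any(means < 1) or np.any(means > 5):
        raise WeightError(f"mean scores must lie in [1, 5]: {dict(mean_scores)}")
    n = len(keys)
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = int(np.clip(round(means[i] - means[j]), -4, 4))
            a = _DIFF_TO_SAATY[abs(d)]
            if d >= 0:
                A[i, j], A[j, i] = a, 1.0 / a
            else:
                A[i, j], A[j, i] = 1.0 / a, a
    return PairwiseMatrix(entries=A, keys=tuple(keys))


def principal_weights(
    M: PairwiseMatrix,
    *,
    method: str = "eigenvector",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> AhpResult:
    """AHP weights from a judgment matrix, with the CR consistency test.

    ``method="eigenvector"`` (default) runs power iteration on the raw
    matrix to the principal eigenvector; ``method="geometric"`` uses the
    row-geometric-mean approximation.  lambda_max is estimated from the
    returned weights; CR uses the Saaty random indices, with CR := 0 for
    n <= 2 (such matrices are always consistent).
    """
    A = M.entries
    n = M.n
    if method == "geometric":
        w = np.exp(np.log(A).mean(axis=1))
        w = w / w.sum()
    elif method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            w_new = A @ w
            w_new = w_new / w_new.sum()
            if np.max(np.abs(w_new - w)) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise WeightError(
                f"power iteration did not converge in {max_iter} iterations"
            )
    else:
        raise WeightError(f"unknown method {method!r}")

    lambda_max = float(np.mean((A @ w) / w))
    ci = (lambda_max - n) / (n - 1) if n >= 2 else 0.0
    if n <= 2:
        cr = 0.0
    else:
        ri = SAATY_RI.get(n)
        if ri is None:
            raise WeightError(f"no Saaty random index tabulated for n={n}")
        cr = ci / ri
    weights = WeightVector({k: float(v) for k, v in zip(M.keys, w)})
    return AhpResult(
        weights=weights,
        lambda_max=lambda_max,
        ci=float(ci),
        cr=float(cr),
        consistent=bool(cr < 0.1),
    )


def combine_weights(w_a: WeightVector, w_b: WeightVector, alpha: float) -> WeightVector:
    """Convex combination alpha*w_a + (1-alpha)*w_b, renormalized."""
    if not (0.0 <= alpha <= 1.0):
        raise WeightError(f"alpha must be in [0, 1], got {alpha}")
    if set(w_a.keys) != set(w_b.keys):
        raise WeightError(
            f"key mismatch: {sorted(w_a.keys)} vs {sorted(w_b.keys)}"
        )
    combined = {k: alpha * w_a[k] + (1 - alpha) * w_b[k] for k in w_a.keys}
    return WeightVector(combined)
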