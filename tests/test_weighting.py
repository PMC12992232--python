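"""Entropy weight method, AHP, and weight combination.

The entropy implementation is checked against a brute-force loop oracle
that evaluates the textbook formulas term by term; the AHP principal
eigenvector is checked against numpy's dense eigensolver.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzymcda import (
    PairwiseMatrix,
    RawIndicatorMatrix,
    WeightError,
    WeightVector,
    combine_weights,
    entropy_weights,
    likert_to_pairwise,
    minmax_normalize,
    principal_weights,
)


def entropy_oracle(Y: np.ndarray):
    """Brute-force information-entropy weights from a normalized matrix."""
    n, k = Y.shape
    P = np.zeros_like(Y)
    for j in range(k):
        s = Y[:, j].sum()
        if s > 0:
            P[:, j] = Y[:, j] / s
    E = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for i in range(n):
            if P[i, j] > 0:
                acc += P[i, j] * math.log(P[i, j])
        E[j] = -acc / math.log(n)
    W = (1 - E) / (k - E.sum())
    return E, W


def eig_oracle(A: np.ndarray) -> np.ndarray:
    """Principal eigenvector of a positive matrix via the dense eigensolver."""
    vals, vecs = np.linalg.eig(A)
    v = np.real(vecs[:, np.argmax(np.real(vals))])
    v = np.abs(v)
    return v / v.sum()


class TestMinMaxNormalize:
    def test_positive_direction(self):
        X = RawIndicatorMatrix(values=pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert list(minmax_normalize(X)["a"]) == [0.0, 0.5, 1.0]

    def test_negative_direction_mirrors(self):
        X = RawIndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 2.0, 3.0]}), directions={"a": "negative"}
        )
        assert list(minmax_normalize(X)["a"]) == [1.0, 0.5, 0.0]

    def test_constant_column_policy(self):
        X = RawIndicatorMatrix(values=pd.DataFrame({"a": [4.0, 4.0, 4.0]}))
        with pytest.warns(UserWarning, match="constant"):
            Y = minmax_normalize(X)
        assert list(Y["a"]) == [0.5, 0.5, 0.5]


class TestEntropyWeights:
    def test_hand_computed_example(self):
        # one informative column, one constant: E = (0.5794, 1), W = (1, 0)
        X = RawIndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        )
        with pytest.warns(UserWarning):
            res = entropy_weights(X)
        assert res.entropies["a"] == pytest.approx(0.5794, abs=1e-4)
        assert res.entropies["b"] == 1.0
        assert res.weights["a"] == pytest.approx(1.0, abs=1e-12)
        assert res.weights["b"] == 0.0

    def test_identical_columns_share_weight(self):
        X = RawIndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [10.0, 50.0, 20.0]})
        )
        res = entropy_weights(X)
        assert res.weights["a"] == pytest.approx(0.5, abs=1e-12)

    def test_single_indicator_gets_all_weight(self):
        X = RawIndicatorMatrix(values=pd.DataFrame({"a": [1.0, 3.0, 2.0]}))
        assert entropy_weights(X).weights["a"] == pytest.approx(1.0)

    def test_all_uniform_is_error(self):
        X = RawIndicatorMatrix(
            values=pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        )
        with pytest.warns(UserWarning):
            with pytest.raises(WeightError, match="no discriminating"):
                entropy_weights(X)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(3, 7), rng.integers(3, 7)
        X = RawIndicatorMatrix(
            values=pd.DataFrame(
                rng.random((n, k)) * 10, columns=[f"i{j}" for j in range(k)]
            )
        )
        res = entropy_weights(X)
        E, W = entropy_oracle(res.normalized.to_numpy())
        assert np.allclose(res.entropies.to_numpy(), E, atol=1e-12)
        assert np.allclose(res.weights.values, W, atol=1e-12)

    def test_scale_invariance_under_affine_transform(self):
        rng = np.random.default_rng(11)
        base = rng.random((6, 3))
        X1 = RawIndicatorMatrix(values=pd.DataFrame(base, columns=list("abc")))
        scaled = base.copy()
        scaled[:, 1] = 100.0 * scaled[:, 1] + 7.0
        X2 = RawIndicatorMatrix(values=pd.DataFrame(scaled, columns=list("abc")))
        assert np.allclose(
            entropy_weights(X1).weights.values,
            entropy_weights(X2).weights.values,
            atol=1e-12,
        )

    def test_proportion_columns_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = RawIndicatorMatrix(values=pd.DataFrame(rng.random((5, 4))))
        res = entropy_weights(X)
        assert np.allclose(res.proportions.sum(axis=0), 1.0, atol=1e-9)
        assert res.weights.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((res.entropies >= 0) & (res.entropies <= 1 + 1e-12)).all()

    def test_dispersion_monotonicity(self):
        # concentrating one column's mass (holding others fixed) raises its weight
        others = np.linspace(0, 1, 8)
        flat = np.linspace(0, 1, 8)  # near-uniform
        skewed = np.array([0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 1.0])
        w_flat = entropy_weights(
            RawIndicatorMatrix(values=pd.DataFrame({"x": flat, "o": others}))
        ).weights["x"]
        w_skew = entropy_weights(
            RawIndicatorMatrix(values=pd.DataFrame({"x": skewed, "o": others}))
        ).weights["x"]
        assert w_skew > w_flat


class TestLikertToPairwise:
    def test_equal_means_identity(self):
        M = likert_to_pairwise({"a": 3.0, "b": 3.0})
        assert np.allclose(M.entries, 1.0)

    def test_extreme_difference_maps_to_nine(self):
        M = likert_to_pairwise({"a": 5.0, "b": 1.0})
        assert M.entries[0, 1] == 9.0
        assert M.entries[1, 0] == pytest.approx(1 / 9)

    def test_graded_differences(self):
        M = likert_to_pairwise({"a": 4.0, "b": 3.0, "c": 2.0})
        assert M.entries[0, 1] == 3.0
        assert M.entries[1, 2] == 3.0
        assert M.entries[0, 2] == 5.0

    def test_empty_group_is_error(self):
        with pytest.raises(WeightError, match="empty"):
            likert_to_pairwise({})

    def test_out_of_range_mean_is_error(self):
        with pytest.raises(WeightError):
            likert_to_pairwise({"a": 0.5, "b": 3.0})


class TestPrincipalWeights:
    def test_consistent_2x2_closed_form(self):
        M = PairwiseMatrix(entries=np.array([[1.0, 2.0], [0.5, 1.0]]), keys=("a", "b"))
        res = principal_weights(M)
        assert res.weights["a"] == pytest.approx(2 / 3, abs=1e-10)
        assert res.cr == 0.0
        assert res.consistent

    def test_3x3_against_dense_eigensolver(self):
        A = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1.0]])
        res = principal_weights(PairwiseMatrix(entries=A, keys=("a", "b", "c")))
        assert np.allclose(res.weights.values, eig_oracle(A), atol=1e-8)
        assert res.weights.values == pytest.approx([0.637, 0.258, 0.105], abs=1e-3)
        assert res.cr == pytest.approx(0.033, abs=2e-3)
        assert res.consistent

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_recovers_weights_of_consistent_matrix(self, n):
        rng = np.random.default_rng(n)
        w = rng.random(n) + 0.2
        w = w / w.sum()
        ratio = w[:, None] / w[None, :]
        # keep entries on the admissible Saaty range
        if ratio.max() > 9:
            w = 0.5 * w + 0.5 / n
            w = w / w.sum()
            ratio = w[:, None] / w[None, :]
        res = principal_weights(PairwiseMatrix(entries=ratio, keys=tuple(map(str, range(n)))))
        assert np.allclose(res.weights.values, w, atol=1e-8)
        assert abs(res.cr) < 1e-8
        assert res.lambda_max == pytest.approx(n, abs=1e-6)

    def test_geometric_mean_variant_close_to_eigenvector(self):
        A = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1.0]])
        M = PairwiseMatrix(entries=A, keys=("a", "b", "c"))
        w_eig = principal_weights(M).weights.values
        w_geo = principal_weights(M, method="geometric").weights.values
        assert np.allclose(w_eig, w_geo, atol=0.01)

    def test_non_reciprocal_matrix_rejected(self):
        with pytest.raises(WeightError, match="reciprocal"):
            PairwiseMatrix(entries=np.array([[1.0, 2.0], [2.0, 1.0]]), keys=("a", "b"))

    def test_entries_outside_saaty_range_rejected(self):
        with pytest.raises(WeightError):
            PairwiseMatrix(entries=np.array([[1.0, 12.0], [1 / 12, 1.0]]), keys=("a", "b"))


class TestCombineWeights:
    @given(alpha=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=25)
    def test_convex_combination(self, alpha):
        wa = WeightVector({"x": 0.6, "y": 0.4})
        wb = WeightVector({"x": 0.2, "y": 0.8})
        wc = combine_weights(wa, wb, alpha)
        assert wc["x"] == pytest.approx(alpha * 0.6 + (1 - alpha) * 0.2, abs=1e-12)
        assert wc.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_example(self):
        wc = combine_weights(
            WeightVector({"x": 0.6, "y": 0.4}), WeightVector({"x": 0.2, "y": 0.8}), 0.5
        )
        assert wc.as_dict() == pytest.approx({"x": 0.4, "y": 0.6})

    def test_key_mismatch_is_error(self):
        with pytest.raises(WeightError, match="mismatch"):
            combine_weights(
                WeightVector({"x": 1.0}), WeightVector({"z": 1.0}), 0.5
            )
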