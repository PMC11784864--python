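"""Metrics against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragdta.metrics import (
    UndefinedMetricError,
    aupr,
    auroc,
    concordance_index,
    mse,
    rm_squared,
)


def brute_force_ci(y, yhat):
    num = den = 0.0
    for a in range(len(y)):
        for b in range(len(y)):
            if y[a] > y[b]:
                den += 1
                if yhat[a] > yhat[b]:
                    num += 1
                elif yhat[a] == yhat[b]:
                    num += 0.5
    return num / den


def brute_force_auroc(y, s):
    pos = [s[i] for i in range(len(y)) if y[i] == 1]
    neg = [s[i] for i in range(len(y)) if y[i] == 0]
    num = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestConcordanceIndex:
    @pytest.mark.parametrize(
        "y,yhat,expected",
        [
            ([1, 2, 3], [0.1, 0.2, 0.3], 1.0),
            ([1, 2, 3], [3, 2, 1], 0.0),
            ([1, 2, 3], [1, 3, 2], 2 / 3),
            ([1, 2], [5, 5], 0.5),  # predicted tie scores one half
        ],
    )
    def test_examples(self, y, yhat, expected):
        assert concordance_index(y, yhat) == pytest.approx(expected)

    def test_all_labels_equal_raises(self):
        with pytest.raises(UndefinedMetricError):
            concordance_index([2, 2, 2], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 5, size=12).astype(float)
        if len(np.unique(y)) < 2:
            y[0] += 1
        yhat = rng.normal(size=12).round(1)
        assert concordance_index(y, yhat) == pytest.approx(brute_force_ci(y, yhat))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=15)
        yhat = rng.normal(size=15)
        for transform in (lambda s: 3 * s + 2, np.exp, lambda s: s ** 3):
            assert concordance_index(y, transform(yhat)) == pytest.approx(
                concordance_index(y, yhat)
            )


class TestRmSquared:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.5])
        assert rm_squared(y, y) == pytest.approx(1.0)

    def test_constant_shift_penalized(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = y + 2.0
        # reference evaluation of the formula itself
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        k = np.sum(y * yhat) / np.sum(yhat ** 2)
        r0 = 1 - np.sum((y - k * yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        expected = r2 * (1 - np.sqrt(abs(r2 - r0)))
        got = rm_squared(y, yhat)
        assert got == pytest.approx(expected)
        assert got < 1.0

    def test_uncorrelated_noise_near_zero(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=4000)
        yhat = rng.normal(size=4000)
        assert abs(rm_squared(y, yhat)) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            rm_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_never_exceeds_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=20)
        yhat = y + rng.normal(scale=0.5, size=20)
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        assert rm_squared(y, yhat) <= r2 + 1e-12


class TestAupr:
    def test_perfect_separation(self):
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], threshold=0.5) == pytest.approx(1.0)

    def test_scores_equal_labels(self):
        y = [3.0, 7.0, 9.0, 2.0]
        assert aupr(y, y, threshold=5.0) == pytest.approx(1.0)

    def test_four_point_toy(self):
        # labels 1,1,0,0; scores .9,.4,.6,.1; descending: .9(P),.6(N),.4(P),.1(N)
        # AP = 1.0 * 0.5 + (2/3) * 0.5 = 5/6
        assert aupr([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], threshold=0.5) == pytest.approx(5 / 6)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            aupr([1, 2, 3], [0.1, 0.2, 0.3], threshold=0.0)


class TestAuroc:
    def test_separated(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_identical_scores_half(self):
        assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_three_pos_three_neg_toy(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.4, 0.6, 0.5, 0.5, 0.1]
        assert auroc(y, s) == pytest.approx(brute_force_auroc(y, s))

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_pairwise_oracle_matches_roc_integration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.normal(size=n).round(1)
        assert auroc(y, s) == pytest.approx(brute_force_auroc(y, s), abs=1e-12)


def test_mse_basic():
    assert mse([1.0, 2.0], [1.5, 1.5]) == pytest.approx(0.25)
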