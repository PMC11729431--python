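import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from erfesim.biomarkers import (
    biomarker_table,
    correlate,
    delta_erfe,
    is_hyporesponder,
    relative_delta,
    roc,
)
from erfesim.synthetic import make_dataset, make_hyporesponder_cohort


class TestDeltaErfe:
    def test_simple_change(self):
        assert delta_erfe([0, 4], [7.0, 10.0]) == pytest.approx(3.0)

    def test_flat_series_zero(self):
        assert delta_erfe([0, 1, 4, 8], [6.0] * 4) == 0.0

    def test_interpolates_off_grid_offset(self):
        assert delta_erfe([0, 2, 6], [5.0, 7.0, 11.0], at=4.0) == pytest.approx(4.0)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            delta_erfe([1, 4], [7.0, 9.0])

    def test_offset_outside_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            delta_erfe([0, 2], [7.0, 9.0], at=4.0)

    def test_relative_change_formula(self):
        assert relative_delta(2.0, 8.0) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            relative_delta(1.0, 0.0)


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 10.0)
        res = correlate(x, 2.0 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_orthogonal_vectors_give_zero_r(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert correlate(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        r = correlate(x, y).r
        direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0, np.inf], [1.0, 2.0, 3.0])


def _pair_count_auc(scores, labels):
    """Concordant-pair fraction with ties counting one half."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1.0, 2.0, 3.0, 10.0, 11.0], [False, False, False, True, True])
        assert res.auc == pytest.approx(1.0)
        assert res.j_index == pytest.approx(1.0)
        assert 3.0 < res.cutoff < 10.0

    def test_identical_scores_give_half(self):
        res = roc([5.0] * 6, [True, False, True, False, True, False])
        assert res.auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, size=9).astype(float)
            labels = rng.uniform(size=9) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc(scores, labels).auc == pytest.approx(
                _pair_count_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_auc(self, rng):
        scores = rng.normal(size=25)
        labels = rng.uniform(size=25) < 0.5
        labels[0], labels[1] = True, False
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_positive_low_orientation(self, rng):
        scores = rng.normal(size=15)
        labels = scores < -0.2  # low scores are the positives
        res = roc(scores, labels, positive_low=True)
        assert res.auc == pytest.approx(roc(-scores, labels).auc, abs=1e-12)
        assert res.auc > 0.99
        # cutoff reported on the original scale near the class boundary
        assert scores[labels].max() <= res.cutoff <= scores[~labels].min()

    @given(
        st.lists(st.integers(min_value=-500, max_value=500), min_size=4, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_auc_invariant_under_monotone_transforms(self, scores, rnd):
        # decimal-quantized scores keep transforms strictly monotone in
        # float arithmetic (no underflow-induced ties)
        scores = np.asarray(scores, dtype=float) / 10.0
        labels = np.array([rnd.random() < 0.5 for _ in scores])
        if labels.all() or not labels.any():
            labels[0] = True
            labels[-1] = False
        base = roc(scores, labels).auc
        for transform in (lambda s: 3.0 * s + 7.0, np.exp, lambda s: s**3):
            assert roc(transform(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert 0.0 <= base <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1.0, 2.0], [True, True])


def test_hyporesponder_rule_boundary():
    assert is_hyporesponder(0.99)
    assert not is_hyporesponder(1.0)  # exactly 1 g/dL gain is a responder
    assert not is_hyporesponder(2.5)


def test_biomarker_direction_on_hyporesponder_cohort(pk_config):
    """Subjects with larger early ERFE induction gain more HGB; the 4-h
    ERFE change discriminates the generative hyporesponder phenotype."""
    severities = np.linspace(0.05, 0.95, 10)
    cohort = make_hyporesponder_cohort(10, seed=21, severities=severities)
    dataset = make_dataset(cohort, "hyporesponder_study", seed=21, pk_config=pk_config)
    table = biomarker_table(dataset, dose_time=192.0, hgb_window_h=144.0)
    assert len(table) == 10
    res = correlate(table["delta_erfe_4h"], table["delta_hgb"])
    assert res.slope > 0 and res.r > 0
    truth = np.array([s.true_hyporesponder for s in cohort])
    auc = roc(table["delta_erfe_4h"].to_numpy(), truth, positive_low=True).auc
    assert auc > 0.5
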