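"""Signal-detection-theory primitives: detectability, AUC, cut-offs, ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metaroi.sdt import (
    GaussianPair,
    GroupStats,
    _density_crossings,
    auc_from_d,
    criterion_performance,
    cumulative_distribution,
    cutoff_for_sensitivity,
    d_from_auc,
    detectability_index,
    empirical_roc,
    ideal_observer_cutoff,
    percent_change,
)

ENT_AD = GroupStats(2.743, 0.458)
ENT_NC = GroupStats(3.370, 0.278)
HIP_AD = GroupStats(5962.1, 1025.3)
HIP_NC = GroupStats(7238.4, 870.0)


class TestDetectabilityIndex:
    @pytest.mark.parametrize(
        "signal, background, expected",
        [
            (ENT_AD, ENT_NC, 1.655),   # entorhinal thickness, AD vs NC
            (HIP_AD, HIP_NC, 1.342),   # hippocampal volume, AD vs NC
            (GroupStats(5.0, 1.3), GroupStats(5.0, 1.3), 0.0),
        ],
    )
    def test_reference_values(self, signal, background, expected):
        assert detectability_index(signal, background) == pytest.approx(
            expected, abs=5e-4
        )

    def test_antisymmetric_in_group_order(self):
        assert detectability_index(ENT_AD, ENT_NC) == pytest.approx(
            -detectability_index(ENT_NC, ENT_AD)
        )

    def test_rejects_non_positive_sd(self):
        with pytest.raises(ValueError, match="sd"):
            GroupStats(1.0, 0.0)
        with pytest.raises(ValueError, match="sd"):
            GroupStats(1.0, -0.2)


class TestAucConversions:
    @pytest.mark.parametrize(
        "d, auc, tol",
        [
            (1.655, 0.879, 5e-4),    # published entorhinal thickness AUC
            (0.0, 0.5, 1e-12),
            (1.342, 0.829, 1e-3),    # hippocampus: published 0.828, formula 0.829
        ],
    )
    def test_forward(self, d, auc, tol):
        assert auc_from_d(d) == pytest.approx(auc, abs=tol)

    def test_inverse_of_published_auc(self):
        assert d_from_auc(0.879) == pytest.approx(1.655, abs=2e-3)
        assert d_from_auc(0.5) == 0.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_inverse_domain(self, bad):
        with pytest.raises(ValueError):
            d_from_auc(bad)

    def test_non_finite_d_rejected(self):
        with pytest.raises(ValueError):
            auc_from_d(float("nan"))

    @given(st.floats(-6, 6))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, d):
        assert d_from_auc(auc_from_d(d)) == pytest.approx(d, abs=1e-10)

    @given(st.floats(-6, 6))
    @settings(max_examples=100, deadline=None)
    def test_complement_symmetry(self, d):
        assert auc_from_d(d) + auc_from_d(-d) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-5, 5, 101)
        vals = [auc_from_d(d) for d in grid]
        assert np.all(np.diff(vals) > 0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, cmp, expected",
        [
            (HIP_NC, HIP_AD, -19.3),  # hippocampal volume reduction
            (GroupStats(1500.5, 1066.1), GroupStats(3348.5, 2440.2), 76.2),
            (GroupStats(3.0, 0.1), GroupStats(3.0, 0.1), 0.0),
        ],
    )
    def test_symmetric_convention(self, ref, cmp, expected):
        assert percent_change(ref, cmp) == pytest.approx(expected, abs=0.05)

    def test_plain_convention_differs(self):
        # plain (AD-NC)/NC gives -18.6% for entorhinal thickness, the
        # symmetric midpoint convention -20.5%
        assert percent_change(ENT_NC, ENT_AD, convention="plain") == pytest.approx(
            -18.6, abs=0.05
        )
        assert percent_change(ENT_NC, ENT_AD) == pytest.approx(-20.5, abs=0.05)

    @given(
        st.floats(0.1, 1e4), st.floats(0.1, 1e4),
        st.floats(0.01, 100), st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric(self, m1, m2, s1, s2):
        a, b = GroupStats(m1, s1), GroupStats(m2, s2)
        assert percent_change(a, b) == pytest.approx(-percent_change(b, a), abs=1e-9)

    def test_non_positive_midpoint_rejected(self):
        with pytest.raises(ValueError):
            percent_change(GroupStats(-4.0, 1.0), GroupStats(2.0, 1.0))


class TestIdealObserverCutoff:
    def test_entorhinal_cutoff_matches_published(self):
        pair = GaussianPair(signal=ENT_AD, background=ENT_NC)
        assert round(ideal_observer_cutoff(pair), 2) == 3.04

    def test_entorhinal_rejected_second_root(self):
        roots = _density_crossings(ENT_AD, ENT_NC)
        assert max(roots) == pytest.approx(4.43, abs=5e-3)

    def test_equal_variance_midpoint(self):
        pair = GaussianPair(GroupStats(0.0, 1.0), GroupStats(2.0, 1.0))
        assert ideal_observer_cutoff(pair) == pytest.approx(1.0)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_equal_sd_is_always_midpoint(self, m1, m2, s):
        if abs(m1 - m2) < 1e-6:
            return
        pair = GaussianPair(GroupStats(m1, s), GroupStats(m2, s))
        assert ideal_observer_cutoff(pair) == pytest.approx(
            0.5 * (m1 + m2), abs=1e-9
        )

    def test_identical_distributions_error(self):
        pair = GaussianPair(GroupStats(1.0, 0.5), GroupStats(1.0, 0.5))
        with pytest.raises(ValueError, match="no unique"):
            ideal_observer_cutoff(pair)

    def test_no_between_means_root_names_both_roots(self):
        # narrow background inside a wide signal with close means: both
        # density crossings fall outside the mean interval
        pair = GaussianPair(GroupStats(3.110, 0.463), GroupStats(3.370, 0.278))
        with pytest.raises(ValueError, match="crossings at"):
            ideal_observer_cutoff(pair)

    @pytest.mark.parametrize(
        "signal, background, direction",
        [
            (ENT_AD, ENT_NC, "low"),
            (HIP_AD, HIP_NC, "low"),
            (GroupStats(3348.5, 2440.2), GroupStats(1500.5, 1066.1), "high"),
        ],
    )
    def test_optimality_over_criterion_grid(self, signal, background, direction):
        # the likelihood-ratio criterion maximizes balanced accuracy among
        # single thresholds (ideal-observer optimality under equal priors)
        pair = GaussianPair(signal, background)
        cut = ideal_observer_cutoff(pair)
        _, _, best = criterion_performance(pair, cut, direction)
        pooled = math.sqrt(0.5 * signal.sd**2 + 0.5 * background.sd**2)
        center = 0.5 * (signal.mean + background.mean)
        grid = np.linspace(center - 4 * pooled, center + 4 * pooled, 1000)
        accs = [criterion_performance(pair, c, direction)[2] for c in grid]
        assert best >= max(accs) - 1e-12


class TestCriterionPerformance:
    def test_clinical_trial_balanced_accuracy(self):
        # sensitivity 0.95 with specificity 0.80 averages to 0.875
        assert 0.5 * (0.95 + 0.80) == pytest.approx(0.875)
        pair = GaussianPair(GroupStats(0.0, 1.0), GroupStats(3.0, 1.0))
        cut = cutoff_for_sensitivity(pair.signal, 0.95, "low")
        sens, spec, bal = criterion_performance(pair, cut, "low")
        assert bal == pytest.approx(0.5 * (sens + spec))
        assert sens == pytest.approx(0.95, abs=1e-9)

    def test_half_mass_at_signal_mean(self):
        pair = GaussianPair(GroupStats(2.0, 0.3), GroupStats(4.0, 0.5))
        sens, _, _ = criterion_performance(pair, 2.0, "low")
        assert sens == pytest.approx(0.5)

    def test_entorhinal_cutoff_performance_with_monte_carlo(self):
        pair = GaussianPair(signal=ENT_AD, background=ENT_NC)
        sens, spec, _ = criterion_performance(pair, 3.0388, "low")
        assert sens == pytest.approx(0.74, abs=0.005)
        assert spec == pytest.approx(0.88, abs=0.005)
        rng = np.random.default_rng(42)
        n = 10**6
        mc_sens = np.mean(rng.normal(ENT_AD.mean, ENT_AD.sd, n) <= 3.0388)
        mc_spec = np.mean(rng.normal(ENT_NC.mean, ENT_NC.sd, n) > 3.0388)
        assert sens == pytest.approx(mc_sens, abs=0.005)
        assert spec == pytest.approx(mc_spec, abs=0.005)

    def test_high_direction_swaps_tails(self):
        pair = GaussianPair(GroupStats(4.0, 1.0), GroupStats(2.0, 1.0))
        sens, spec, _ = criterion_performance(pair, 3.0, "high")
        assert sens == pytest.approx(stats.norm.sf(3.0, 4.0, 1.0))
        assert spec == pytest.approx(stats.norm.cdf(3.0, 2.0, 1.0))


class TestCutoffForSensitivity:
    def test_median_criterion(self):
        assert cutoff_for_sensitivity(GroupStats(0.0, 1.0), 0.5, "low") == pytest.approx(0.0)

    def test_95_percent_sensitivity_quantile(self):
        cut = cutoff_for_sensitivity(ENT_AD, 0.95, "low")
        assert cut == pytest.approx(2.743 + 1.6449 * 0.458, abs=1e-3)

    @pytest.mark.parametrize("target", [0.8, 0.95])
    @pytest.mark.parametrize("direction", ["low", "high"])
    def test_round_trip_with_criterion_performance(self, target, direction):
        pair = GaussianPair(GroupStats(1.5, 0.7), GroupStats(4.0, 1.1))
        cut = cutoff_for_sensitivity(pair.signal, target, direction)
        sens, _, _ = criterion_performance(pair, cut, direction)
        assert sens == pytest.approx(target, abs=1e-9)

    def test_out_of_range_target(self):
        with pytest.raises(ValueError):
            cutoff_for_sensitivity(ENT_AD, 1.0, "low")


def _pairwise_auc(scores, labels):
    """Brute-force concordance oracle: P(signal > background) + half ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEmpiricalRoc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),
            ([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1], 0.5),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),  # 3 wins of 4 pairs
        ],
    )
    def test_known_aucs(self, scores, labels, expected):
        curve = empirical_roc(scores, labels)
        assert curve.auc == pytest.approx(expected)
        assert curve.auc == pytest.approx(_pairwise_auc(scores, labels))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 6, n).astype(float)  # many ties
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        assert empirical_roc(scores, labels).auc == pytest.approx(
            _pairwise_auc(scores, labels)
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.normal(size=200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100)
        assert empirical_roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_geometry(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 4, 50).astype(float)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        curve = empirical_roc(scores, labels)
        pts = curve.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        assert curve.auc == pytest.approx(
            np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, 120)
        labels[:2] = [0, 1]
        base = empirical_roc(scores, labels).auc
        assert empirical_roc(np.exp(scores), labels).auc == pytest.approx(base)
        assert empirical_roc(3 * scores - 7, labels).auc == pytest.approx(base)

    def test_low_direction_flips(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [1, 1, 0, 0]
        assert empirical_roc(scores, labels, direction="low").auc == 1.0

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1.0, 2.0], [1, 1])

    def test_large_sample_agrees_with_binormal(self):
        # empirical AUC on 1e5/group Gaussian draws vs the closed form
        rng = np.random.default_rng(7)
        n = 10**5
        scores = np.r_[
            rng.normal(ENT_NC.mean, ENT_NC.sd, n),
            rng.normal(ENT_AD.mean, ENT_AD.sd, n),
        ]
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        target = auc_from_d(abs(detectability_index(ENT_AD, ENT_NC)))
        assert empirical_roc(scores, labels, direction="low").auc == pytest.approx(
            target, abs=0.01
        )


class TestCumulativeDistribution:
    def test_counting(self):
        np.testing.assert_array_equal(
            cumulative_distribution([1, 2, 3], [0, 2, 4]), [0.0, 2.0, 3.0]
        )

    def test_normalized_terminates_at_one(self):
        out = cumulative_distribution([5.0, 1.0, 2.5], [0, 1, 3, 10], normalized=True)
        assert out[-1] == 1.0
        assert np.all(np.diff(out) >= 0)

    def test_empirical_cdf_converges_to_gaussian(self):
        rng = np.random.default_rng(13)
        mu, sigma = 2.743, 0.458
        sample = rng.normal(mu, sigma, 10**5)
        grid = np.linspace(mu - 4 * sigma, mu + 4 * sigma, 200)
        cdf = cumulative_distribution(sample, grid, normalized=True)
        assert np.max(np.abs(cdf - stats.norm.cdf(grid, mu, sigma))) < 0.01

    def test_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            cumulative_distribution([1.0], [2.0, 1.0])
        with pytest.raises(ValueError, match="value"):
            cumulative_distribution([], [0.0, 1.0])
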