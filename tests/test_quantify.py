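"""Frequencies, angular transform, slopes, classification, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clscreen.counts import AmplificationCallSet, CountTensor, call_amplified
from clscreen.quantify import (
    FrequencyMatrix,
    angular_transform,
    classify_strains,
    compute_frequencies,
    expected_overlap,
    fit_strain_slopes,
    overlap_stats,
)


class TestAngularTransform:
    @pytest.mark.parametrize("p, theta", [(0.0, 0.0), (0.5, 45.0), (1.0, 90.0)])
    def test_closed_forms_in_degrees(self, p, theta):
        assert angular_transform(p) == pytest.approx(theta, abs=1e-12)

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(0.01, 0.99, 99)
        theta = angular_transform(grid)
        assert np.all(np.diff(theta) > 0)

    def test_radians_option(self):
        assert angular_transform(0.5, degrees=False) == pytest.approx(np.pi / 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            angular_transform(1.2)


class TestComputeFrequencies:
    def test_frequencies_sum_to_one_per_sample(self, small_screen):
        tensor, _ = small_screen
        freqs = compute_frequencies(tensor)
        assert np.allclose(freqs.freq.sum(axis=0), 1.0)

    def test_zero_count_maps_to_zero_degrees(self, toy_tensor):
        tensor = CountTensor(np.array([[[[0, 5]]], [[[10, 5]]]]),
                             ["A", "B"], ["H"], [1], [0.0, 7.0])
        freqs = compute_frequencies(tensor)
        assert freqs.theta[0, 0, 0, 0] == 0.0

    def test_zero_total_sample_error_names_sample(self):
        tensor = CountTensor(np.array([[[[0, 5]]]]), ["A"], ["H"], [1], [0.0, 7.0])
        with pytest.raises(ValueError, match=r"environment=H.*timepoint=0"):
            compute_frequencies(tensor)

    def test_anscombe_variant_avoids_exact_zero(self):
        tensor = CountTensor(np.array([[[[0, 5]]], [[[10, 5]]]]),
                             ["A", "B"], ["H"], [1], [0.0, 7.0])
        freqs = compute_frequencies(tensor, anscombe=True)
        assert freqs.freq[0, 0, 0, 0] == pytest.approx(0.375 / 10.75)
        assert freqs.theta[0, 0, 0, 0] > 0


def _freq_from_theta(theta, timepoints):
    """Wrap a theta array (strain, env, rep, time) as a FrequencyMatrix."""
    theta = np.asarray(theta, dtype=float)
    s, e, r, t = theta.shape
    p = np.sin(np.radians(theta)) ** 2
    return FrequencyMatrix(p, theta, [f"S{i}" for i in range(s)],
                           ["H", "G"][:e], list(range(1, r + 1)),
                           list(timepoints))


class TestFitStrainSlopes:
    days = (0.0, 7.0, 14.0, 21.0, 28.0)

    def test_constant_series_slope_zero(self):
        theta = np.full((1, 1, 1, 5), 10.0)
        table = fit_strain_slopes(_freq_from_theta(theta, self.days))
        assert table.replicate_slopes[0, 0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_exact_linear_series_recovers_slope(self):
        t = np.array(self.days)
        theta = (5 + 0.5 * t).reshape(1, 1, 1, 5)
        table = fit_strain_slopes(_freq_from_theta(theta, self.days))
        assert table.replicate_slopes[0, 0, 0] == pytest.approx(0.5, rel=1e-13)
        assert table.replicate_intercepts[0, 0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_matches_closed_form_and_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        t = np.array(self.days)
        theta = rng.uniform(0, 90, size=(4, 2, 3, 5))
        table = fit_strain_slopes(_freq_from_theta(theta, self.days))
        for i in range(4):
            for j in range(2):
                for r in range(3):
                    y = theta[i, j, r]
                    closed = (((t - t.mean()) * (y - y.mean())).sum()
                              / ((t - t.mean()) ** 2).sum())
                    fit = sm.OLS(y, sm.add_constant(t)).fit()
                    assert table.replicate_slopes[i, j, r] == pytest.approx(closed,
                                                                            rel=1e-10)
                    assert table.replicate_slopes[i, j, r] == pytest.approx(
                        fit.params[1], rel=1e-8)

    @given(st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_shift_equivariance(self, shift):
        rng = np.random.default_rng(7)
        theta = rng.uniform(10, 40, size=(2, 2, 2, 5))
        base = fit_strain_slopes(_freq_from_theta(theta, self.days))
        shifted = fit_strain_slopes(
            _freq_from_theta(np.clip(theta + shift, -1e6, 1e6), self.days))
        assert np.allclose(base.replicate_slopes,
                           shifted.replicate_slopes, atol=1e-8)

    def test_missing_replicate_series_excluded_from_mean(self):
        theta = np.zeros((1, 1, 2, 5))
        t = np.array(self.days)
        theta[0, 0, 0] = 5 + 1.0 * t
        theta[0, 0, 1] = np.nan  # fewer than 2 finite points
        table = fit_strain_slopes(_freq_from_theta(theta, self.days))
        assert np.isnan(table.replicate_slopes[0, 0, 1])
        assert table.average_slopes[0, 0] == pytest.approx(1.0)

    def test_average_and_combined_are_replicate_means(self, small_screen):
        tensor, _ = small_screen
        table = fit_strain_slopes(compute_frequencies(tensor))
        assert np.allclose(table.average_slopes,
                           np.nanmean(table.replicate_slopes, axis=2))
        assert np.allclose(table.combined_slopes,
                           np.nanmean(table.replicate_slopes.reshape(100, -1), axis=1))

    def test_requires_two_distinct_timepoints(self):
        theta = np.zeros((1, 1, 1, 2))
        with pytest.raises(ValueError, match="distinct timepoints"):
            fit_strain_slopes(_freq_from_theta(theta, (7.0, 7.0)))


def _calls(strains, envs=("H", "G"), fails=()):
    totals = pd.DataFrame(1000, index=pd.Index(strains, name="strain"),
                          columns=list(envs))
    for strain, env in fails:
        totals.loc[strain, env] = 0
    passes = totals >= 160
    return AmplificationCallSet(totals, passes, 160, list(envs))


def _slope_table(avg_by_env):
    """Build a SlopeTable whose replicate slopes all equal the target means."""
    from clscreen.quantify import SlopeTable

    strains = sorted(avg_by_env)
    envs = ["H", "G"]
    rep = np.zeros((len(strains), 2, 4))
    for i, s in enumerate(strains):
        for j, e in enumerate(envs):
            rep[i, j, :] = avg_by_env[s][j]
    avg = rep.mean(axis=2)
    combined = rep.reshape(len(strains), -1).mean(axis=1)
    return SlopeTable(rep, np.zeros_like(rep), avg, combined, strains, envs,
                      [1, 2, 3, 4])


class TestClassifyStrains:
    def test_double_positive_is_L(self):
        slopes = _slope_table({"A": (1.0, 2.0), "B": (-1.0, 1.0)})
        labels = classify_strains(slopes, _calls(["A", "B"]), n_S=0, n_M=0)
        assert labels.members("L") == ["A"]
        assert labels.labels["B"] == "unclassified"

    def test_toy_ranking_for_S_and_M(self):
        slopes = _slope_table({
            "A": (-3.0, -3.0), "B": (-1.0, -1.0), "C": (0.0, 0.0),
            "D": (1.0, 1.0), "E": (2.0, 2.0),
        })
        labels = classify_strains(slopes, _calls(list("ABCDE")), n_S=1, n_M=1)
        assert labels.members("S") == ["A"]
        assert labels.members("M") == ["C"]
        assert set(labels.members("L")) == {"D", "E"}
        assert labels.labels["B"] == "unclassified"

    def test_partition_covers_dual_passers(self, small_screen):
        tensor, _ = small_screen
        calls = call_amplified(tensor)
        slopes = fit_strain_slopes(compute_frequencies(tensor))
        labels = classify_strains(slopes, calls, n_S=5, n_M=5)
        counts = labels.labels.value_counts()
        assert counts.sum() == len(calls.dual_passing())
        assert counts.get("S", 0) == 5 and counts.get("M", 0) == 5

    def test_only_dual_passers_classified(self):
        slopes = _slope_table({"A": (1.0, 1.0), "B": (1.0, 1.0)})
        calls = _calls(["A", "B"], fails=[("B", "G")])
        labels = classify_strains(slopes, calls, n_S=0, n_M=0)
        assert "B" not in labels.labels.index

    def test_oversized_groups_rejected(self):
        slopes = _slope_table({"A": (-1.0, -1.0), "B": (1.0, 1.0)})
        with pytest.raises(ValueError, match="n_S"):
            classify_strains(slopes, _calls(["A", "B"]), n_S=5, n_M=0)


class TestOverlap:
    def test_paper_scale_expected_overlap(self):
        assert expected_overlap(793, 800, 6712) == pytest.approx(94.52, abs=0.005)

    def test_empty_set_expectation_zero(self):
        assert expected_overlap(0, 800, 6712) == 0.0

    def test_expectation_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 0
        draws = 100_000
        for _ in range(draws):
            a = rng.choice(10, 5, replace=False)
            b = rng.choice(10, 5, replace=False)
            n += len(set(a) & set(b))
        mc = n / draws
        assert expected_overlap(5, 5, 10) == pytest.approx(mc, abs=0.02)

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap(0, 0, 0)

    def test_overlap_stats_counts(self):
        slopes = _slope_table({"A": (1.0, 1.0), "B": (-1.0, 1.0), "C": (1.0, 1.0)})
        calls = _calls(["A", "B", "C"], fails=[("C", "G")])
        stats = overlap_stats(calls, slopes)
        assert (stats.nH, stats.nG, stats.N) == (3, 2, 3)
        assert stats.observed_overlap == 2
        assert stats.expected_overlap == pytest.approx(2.0)
        assert stats.n_double_positive == 1
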