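"""Double-Gaussian activity model: transform, binning, fit, cutoff, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tjkit import (
    ActivityThreshold,
    DataError,
    DoubleGaussianFit,
    FitError,
    GaussianComponent,
    LogDensity,
    ThresholdError,
    activity_threshold,
    build_density,
    classify_genes,
    fit_double_gaussian,
    log2_transform,
    round_half_away,
)
from tjkit.gene_activity import double_gaussian


def make_fit(a_a, mu_a, sd_a, a_i, mu_i, sd_i, metric="tpm"):
    return DoubleGaussianFit(
        metric=metric,
        active=GaussianComponent(a_a, mu_a, sd_a),
        inactive=GaussianComponent(a_i, mu_i, sd_i),
        residual_norm=0.0,
        converged=True,
    )


def curve_ratio(fit, x):
    with np.errstate(divide="ignore"):  # inactive curve underflows in far tails
        return fit.active(x) / fit.inactive(x)


def grid_search_cutoff(fit, ratio, lo=-20.0, hi=40.0, step=1e-4):
    """Brute-force oracle: smallest grid point beyond which the ratio stays >= ratio."""
    xs = np.arange(lo, hi, step)
    ok = curve_ratio(fit, xs) >= ratio
    below = np.flatnonzero(~ok)
    return xs[below[-1]] if below.size else lo


class TestLog2Transform:
    def test_zeros_excluded_without_pseudocount(self):
        table = pd.DataFrame({"gene_id": list("abc"), "tpm": [0.0, 1.0, 8.0],
                              "fpkm": [0.0, 1.0, 8.0]})
        values, n_zero = log2_transform(table, "tpm")
        np.testing.assert_allclose(sorted(values), [0.0, 3.0])
        assert n_zero == 1

    def test_all_zero_table(self):
        table = pd.DataFrame({"gene_id": list("ab"), "tpm": [0.0, 0.0], "fpkm": [0.0, 0.0]})
        values, n_zero = log2_transform(table, "tpm")
        assert values.size == 0 and n_zero == 2

    def test_fractional_value(self):
        table = pd.DataFrame({"gene_id": ["a"], "tpm": [0.5], "fpkm": [0.5]})
        values, _ = log2_transform(table, "fpkm")
        assert values[0] == pytest.approx(-1.0)

    def test_negative_value_names_gene(self):
        table = pd.DataFrame({"gene_id": ["good", "bad"], "tpm": [1.0, -2.0],
                              "fpkm": [1.0, 1.0]})
        with pytest.raises(DataError, match="bad"):
            log2_transform(table, "tpm")

    def test_conservation_with_density(self, expression_table):
        values, n_zero = log2_transform(expression_table, "tpm")
        density = build_density(values)
        assert n_zero + int(density.counts.sum()) == len(expression_table)


class TestDensity:
    def test_rounding_half_away_from_zero(self):
        np.testing.assert_allclose(round_half_away([1.04, 1.05, 1.06]), [1.0, 1.1, 1.1])
        np.testing.assert_allclose(round_half_away([-1.05, -0.25, 0.25], 1),
                                   [-1.1, -0.3, 0.3])

    def test_tally_and_gap_filling(self):
        d = build_density([1.04, 1.06, 1.05])
        np.testing.assert_allclose(d.bin_centers, [1.0, 1.1])
        np.testing.assert_array_equal(d.counts, [1, 2])
        d2 = build_density([0.0, 0.5])  # gap bins present with zero counts
        assert d2.bin_centers.size == 6
        assert d2.counts.sum() == 2

    def test_bin_spacing_is_exactly_one_tenth(self):
        d = build_density(np.linspace(-3, 7, 500))
        np.testing.assert_allclose(np.diff(d.bin_centers), 0.1, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            build_density([])

    def test_histogram_mean_matches_sample(self, rng):
        values = rng.normal(5.0, 1.0, 50000)
        d = build_density(values)
        mean = np.average(d.bin_centers, weights=d.counts)
        assert mean == pytest.approx(5.0, abs=0.05)


class TestDoubleGaussianFit:
    def test_noise_free_parameter_recovery(self):
        centers = np.arange(-40, 91) / 10.0
        counts = double_gaussian(centers, 300.0, 5.0, 1.0, 150.0, 0.0, 1.0)
        fit = fit_double_gaussian(LogDensity("tpm", centers, counts, 0))
        assert fit.converged
        for got, want in [
            (fit.active.amplitude, 300.0), (fit.active.mean, 5.0), (fit.active.sd, 1.0),
            (fit.inactive.amplitude, 150.0), (fit.inactive.sd, 1.0),
        ]:
            assert got == pytest.approx(want, rel=0.01)
        assert fit.inactive.mean == pytest.approx(0.0, abs=0.01)

    def test_labels_by_mean_not_peak_order(self):
        centers = np.arange(-40, 91) / 10.0
        # inactive peak deliberately taller than the active one
        counts = double_gaussian(centers, 120.0, 5.0, 0.8, 400.0, 0.0, 1.2)
        fit = fit_double_gaussian(LogDensity("tpm", centers, counts, 0))
        assert fit.active.mean > fit.inactive.mean
        assert fit.active.mean == pytest.approx(5.0, rel=0.01)

    def test_sampled_density_recovers_means(self, expression_table):
        values, _ = log2_transform(expression_table, "tpm")
        fit = fit_double_gaussian(build_density(values))
        assert fit.active.mean == pytest.approx(6.0, abs=0.1)
        assert fit.inactive.mean == pytest.approx(0.0, abs=0.1)

    def test_unimodal_density_is_degenerate(self):
        centers = np.arange(-40, 41) / 10.0
        counts = 200.0 * np.exp(-(centers**2) / 2.0)
        density = LogDensity("tpm", centers, counts, 0)
        try:
            fit = fit_double_gaussian(density)
        except FitError:
            return  # degenerate-fit error is acceptable
        small = min(fit.active.amplitude, fit.inactive.amplitude)
        assert small < 0.05 * max(fit.active.amplitude, fit.inactive.amplitude)

    def test_too_few_bins_rejected(self):
        density = LogDensity("tpm", np.arange(5) / 10.0, np.ones(5), 0)
        with pytest.raises(DataError):
            fit_double_gaussian(density)


class TestActivityThreshold:
    def test_equal_sigma_closed_form(self):
        # amplitudes 0.7/0.3, means 5/0, sd 1: x* = 2.5 + ln(5*0.3/0.7)/5
        fit = make_fit(0.7, 5.0, 1.0, 0.3, 0.0, 1.0)
        thr = activity_threshold(fit, ratio=5.0)
        expected = (25.0 + 2.0 * np.log(5.0 * 0.3 / 0.7)) / 10.0
        assert thr.cutoff_log2 == pytest.approx(expected, abs=1e-9)
        assert thr.cutoff_log2 == pytest.approx(2.652, abs=5e-4)

    def test_ratio_one_symmetric_midpoint(self):
        fit = make_fit(100.0, 4.0, 1.0, 100.0, 0.0, 1.0)
        assert activity_threshold(fit, ratio=1.0).cutoff_log2 == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "params",
        [
            (300.0, 5.0, 1.0, 150.0, 0.0, 1.0),
            (0.7, 5.0, 1.0, 0.3, 0.0, 1.0),
            (200.0, 6.0, 1.4, 400.0, 0.5, 0.9),  # wider active component
            (150.0, 4.0, 0.999, 300.0, 0.0, 1.0),  # marginally narrower active
        ],
    )
    def test_defining_property_and_grid_oracle(self, params):
        fit = make_fit(*params)
        thr = activity_threshold(fit, ratio=5.0)
        # the defining property: curve ratio equals 5 at the cutoff ...
        assert curve_ratio(fit, thr.cutoff_log2) == pytest.approx(5.0, rel=1e-6)
        # ... and stays >= 5 just beyond it
        assert np.all(curve_ratio(fit, thr.cutoff_log2 + np.linspace(1e-6, 5.0, 64)) >= 5.0 * (1 - 1e-9))
        # brute-force grid search at 1e-4 resolution agrees
        assert thr.cutoff_log2 == pytest.approx(grid_search_cutoff(fit, 5.0), abs=2e-4)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(min_value=1.5, max_value=8.0),
        st.floats(min_value=0.5, max_value=1.5),
        st.floats(min_value=1.0, max_value=20.0),
    )
    def test_monotone_in_ratio(self, mu_a, sd, ratio):
        fit = make_fit(250.0, mu_a, sd, 400.0, 0.0, sd)
        lo = activity_threshold(fit, ratio=ratio).cutoff_log2
        hi = activity_threshold(fit, ratio=ratio * 1.5).cutoff_log2
        assert hi >= lo

    def test_narrow_active_component_errors_when_ratio_collapses(self):
        # active sd much smaller: the curve ratio falls below 5 well inside
        # the fitted support, so no right-tail cutoff exists
        fit = make_fit(300.0, 3.0, 0.5, 100.0, 0.0, 2.0)
        assert curve_ratio(fit, 3.0 + 4.0) < 5.0
        with pytest.raises(ThresholdError):
            activity_threshold(fit, ratio=5.0)

    def test_unconverged_fit_rejected(self):
        fit = DoubleGaussianFit("tpm", GaussianComponent(1, 5, 1),
                                GaussianComponent(1, 0, 1), 0.0, converged=False)
        with pytest.raises(ThresholdError):
            activity_threshold(fit)


class TestClassifyGenes:
    @staticmethod
    def _thresholds(cut_tpm=2.0, cut_fpkm=2.0):
        return (ActivityThreshold("tpm", cut_tpm, 5.0),
                ActivityThreshold("fpkm", cut_fpkm, 5.0))

    def test_strict_inequality_at_cutoff(self):
        table = pd.DataFrame({"gene_id": ["at", "above"], "tpm": [4.0, 4.1],
                              "fpkm": [4.0, 4.1]})
        thr_tpm, thr_fpkm = self._thresholds()  # cutoff log2 = 2.0 -> tpm 4.0
        calls = classify_genes(table, thr_tpm, thr_fpkm)
        assert list(calls["call_tpm"]) == ["inactive", "active"]
        assert list(calls["call_combined"]) == ["inactive", "active"]

    def test_zero_in_one_metric_zeroes_combined(self):
        table = pd.DataFrame({"gene_id": ["g"], "tpm": [0.0], "fpkm": [100.0]})
        calls = classify_genes(table, *self._thresholds())
        assert calls.loc[0, "call_tpm"] == "zero"
        assert calls.loc[0, "call_fpkm"] == "active"
        assert calls.loc[0, "call_combined"] == "zero"

    def test_combined_conjunction_vs_either(self):
        table = pd.DataFrame({"gene_id": ["g"], "tpm": [100.0], "fpkm": [1.0]})
        thr = self._thresholds()
        assert classify_genes(table, *thr, combine="both").loc[0, "call_combined"] == "inactive"
        assert classify_genes(table, *thr, combine="either").loc[0, "call_combined"] == "active"

    def test_metric_mismatch_rejected(self):
        table = pd.DataFrame({"gene_id": ["g"], "tpm": [1.0], "fpkm": [1.0]})
        thr_tpm, thr_fpkm = self._thresholds()
        with pytest.raises(DataError):
            classify_genes(table, thr_fpkm, thr_tpm)

    def test_end_to_end_accuracy_vs_truth(self, expression_table):
        thresholds = {}
        for metric in ("tpm", "fpkm"):
            values, _ = log2_transform(expression_table, metric)
            fit = fit_double_gaussian(build_density(values, metric))
            thresholds[metric] = activity_threshold(fit, ratio=5.0)
        calls = classify_genes(expression_table, thresholds["tpm"], thresholds["fpkm"])
        accuracy = (calls["call_combined"].to_numpy()
                    == expression_table["truth_label"].to_numpy()).mean()
        assert accuracy >= 0.99
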