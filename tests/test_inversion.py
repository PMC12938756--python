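"""Histogram inversion: fit recovery, derived parameters, quality filter."""

import numpy as np
import pytest

from neotrs import (
    FitResult,
    InstrumentResponse,
    OpticalProperties,
    TimeAxis,
    TimeHistogram,
    attenuation,
    count_rate,
    fit_tpsf,
    mean_path_length,
    merge_segments,
    quality_filter,
)
from neotrs.cohort import inject_unstable_segment


class TestFit:
    def test_noise_free_recovery(self, axis, geometry, irf, make_expected):
        """Self-generated noise-free input, init 20% off truth: recovery
        to within 0.1% relative."""
        truth = OpticalProperties(801, 0.012, 0.95)
        hist = make_expected(truth, geometry, axis, irf, 1e6)
        init = OpticalProperties(801, truth.mu_a * 1.2,
                                 truth.mu_s_prime * 0.8)
        fit = fit_tpsf(hist, irf, geometry, init=init)
        assert fit.converged
        assert fit.optics.mu_a == pytest.approx(truth.mu_a, rel=1e-3)
        assert fit.optics.mu_s_prime == pytest.approx(truth.mu_s_prime,
                                                      rel=1e-3)

    def test_poisson_recovery_seed1(self, axis, geometry, irf, make_expected):
        """1e6-count Poisson histogram, seed 1, truth (0.015, 0.8):
        mu_a within 3%, mu_s' within 5%."""
        truth = OpticalProperties(801, 0.015, 0.8)
        clean = make_expected(truth, geometry, axis, irf, 1e6)
        rng = np.random.default_rng(1)
        hist = TimeHistogram(axis, rng.poisson(clean.counts).astype(float),
                             300.0, wavelength_nm=801)
        fit = fit_tpsf(hist, irf, geometry)
        assert fit.converged
        assert fit.optics.mu_a == pytest.approx(truth.mu_a, rel=0.03)
        assert fit.optics.mu_s_prime == pytest.approx(truth.mu_s_prime,
                                                      rel=0.05)

    def test_amplitude_invariance(self, axis, geometry, irf, make_expected):
        """Rescaling the histogram amplitude leaves the optics unchanged."""
        truth = OpticalProperties(801, 0.01, 1.0)
        hist = make_expected(truth, geometry, axis, irf, 1e6)
        big = TimeHistogram(axis, hist.counts * 10.0, 300.0,
                            wavelength_nm=801)
        f1 = fit_tpsf(hist, irf, geometry)
        f2 = fit_tpsf(big, irf, geometry)
        assert f2.optics.mu_a == pytest.approx(f1.optics.mu_a, rel=1e-4)
        assert f2.optics.mu_s_prime == pytest.approx(f1.optics.mu_s_prime,
                                                     rel=1e-4)

    def test_empty_histogram_errors(self, axis, geometry, irf):
        hist = TimeHistogram(axis, np.zeros(axis.n_bins), 300.0)
        with pytest.raises(ValueError, match="empty histogram"):
            fit_tpsf(hist, irf, geometry)

    def test_axis_mismatch_errors(self, axis, geometry, irf):
        other = TimeAxis.regular(500, 20.0)
        hist = TimeHistogram(other, np.ones(500) * 100, 300.0)
        with pytest.raises(ValueError, match="axes differ"):
            fit_tpsf(hist, irf, geometry)


class TestCountRate:
    def test_arithmetic(self, axis):
        counts = np.zeros(axis.n_bins)
        counts[:3] = [100, 200, 300]
        hist = TimeHistogram(axis, counts, 2.0)
        assert count_rate(hist) == pytest.approx(300.0)

    def test_five_minute_example(self, axis):
        counts = np.full(axis.n_bins, 3e8 / axis.n_bins)
        assert count_rate(TimeHistogram(axis, counts, 300.0)) == \
            pytest.approx(1e6)

    def test_zero_counts(self, axis):
        assert count_rate(TimeHistogram(axis, np.zeros(axis.n_bins),
                                        10.0)) == 0.0


class TestAttenuation:
    def _hist(self, axis, total, acq=1.0):
        counts = np.zeros(axis.n_bins)
        counts[0] = total
        return TimeHistogram(axis, counts, acq)

    def test_hand_log10(self, axis):
        irf = InstrumentResponse(axis, np.ones(axis.n_bins),
                                 total_incident=1e8, acquisition_s=1.0)
        assert attenuation(self._hist(axis, 1e5), irf) == pytest.approx(3.0)

    def test_identity_and_log_law(self, axis):
        irf = InstrumentResponse(axis, np.ones(axis.n_bins),
                                 total_incident=1e6, acquisition_s=1.0)
        assert attenuation(self._hist(axis, 1e6), irf) == pytest.approx(0.0)
        a1 = attenuation(self._hist(axis, 1e4), irf)
        a2 = attenuation(self._hist(axis, 1e2), irf)
        assert a2 - a1 == pytest.approx(2.0)

    def test_invariant_under_joint_rescaling(self, axis):
        irf1 = InstrumentResponse(axis, np.ones(axis.n_bins),
                                  total_incident=1e8, acquisition_s=1.0)
        irf2 = InstrumentResponse(axis, np.ones(axis.n_bins),
                                  total_incident=5e8, acquisition_s=5.0)
        h1 = self._hist(axis, 1e5, acq=1.0)
        h2 = self._hist(axis, 5e5, acq=5.0)
        assert attenuation(h1, irf1) == pytest.approx(attenuation(h2, irf2))

    def test_zero_detected_errors(self, axis):
        irf = InstrumentResponse(axis, np.ones(axis.n_bins),
                                 total_incident=1e8)
        with pytest.raises(ValueError, match="zero detected"):
            attenuation(TimeHistogram(axis, np.zeros(axis.n_bins), 1.0), irf)


class TestMeanPathLength:
    def _dummy_fit(self, mu_a=0.01, mu_sp=1.0):
        return FitResult(optics=OpticalProperties(801, mu_a, mu_sp),
                         amplitude=1.0, t_shift_ps=0.0, reduced_chi2=1.0,
                         n_iterations=1, converged=True, fit_window=(0, 10))

    def test_centroid_difference_hand_value(self, geometry):
        """1000 ps centroid delay at n = 1.4 -> 0.299792458/1.4*1000 mm."""
        axis = TimeAxis.regular(400, 10.0)
        irf_counts = np.zeros(400)
        irf_counts[10] = 1.0  # center 105 ps
        hist_counts = np.zeros(400)
        hist_counts[110] = 1.0  # center 1105 ps -> delay 1000 ps
        irf = InstrumentResponse(axis, irf_counts, total_incident=1.0)
        hist = TimeHistogram(axis, hist_counts, 1.0)
        pl = mean_path_length(self._dummy_fit(), hist, irf, geometry)
        assert pl.centroid_mm == pytest.approx(0.299792458 / 1.4 * 1000,
                                               rel=1e-9)
        assert not pl.flagged

    def test_zero_delay_flagged(self, axis, geometry, irf):
        hist = TimeHistogram(axis, irf.counts.copy(), 300.0)
        pl = mean_path_length(self._dummy_fit(), hist, irf, geometry)
        assert pl.centroid_mm == pytest.approx(0.0, abs=1e-9)
        assert pl.flagged

    def test_centroid_matches_model_estimator(self, axis, geometry, irf,
                                              make_expected):
        """On noise-free self-generated data the centroid estimator and
        -d ln R_total/d mu_a agree within 1%."""
        truth = OpticalProperties(801, 0.01, 0.9)
        hist = make_expected(truth, geometry, axis, irf, 1e6)
        fit = fit_tpsf(hist, irf, geometry)
        pl = mean_path_length(fit, hist, irf, geometry)
        assert pl.centroid_mm == pytest.approx(pl.model_mm, rel=0.01)


class TestQualityFilter:
    def _segments(self, axis, n=10, total=1e5):
        # smooth TPSF-like bump; identical across segments
        shape = np.exp(-0.5 * ((axis.centers - 1500.0) / 400.0) ** 2)
        counts = np.round(shape * (total / shape.sum()))
        return [TimeHistogram(axis, counts.copy(), 30.0,
                              segment_id=f"seg{k:02d}")
                for k in range(n)]

    def test_all_equal_all_accepted(self, axis):
        report = quality_filter(self._segments(axis))
        assert len(report.accepted) == 10
        assert not report.rejected

    def test_low_rate_segment_rejected(self, axis):
        segs = self._segments(axis)
        segs = inject_unstable_segment(segs, 3, rate_scale=0.5)
        report = quality_filter(segs, rate_tolerance=0.10)
        assert [r["segment_id"] for r in report.records] == ["seg03"]
        assert report.records[0]["rule"] == "count_rate_deviation"
        assert len(report.accepted) == 9

    def test_spiky_segment_rejected_by_dispersion(self, axis):
        segs = self._segments(axis)
        counts = segs[5].counts.copy()
        # motion-artifact burst near the peak; total rescaled so only the
        # dispersion rule (not the count-rate rule) can fire
        counts[148:153] *= 3
        counts = np.round(counts * (segs[5].counts.sum() / counts.sum()))
        segs[5] = TimeHistogram(axis, counts, 30.0, segment_id="seg05")
        report = quality_filter(segs, rate_tolerance=0.5)
        assert any(r["segment_id"] == "seg05"
                   and r["rule"] == "dispersion_ratio"
                   for r in report.records)

    def test_single_segment_accepted(self, axis):
        report = quality_filter(self._segments(axis, n=1))
        assert len(report.accepted) == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="at least one segment"):
            quality_filter([])


def test_merge_segments_sums_counts_and_time(axis):
    segs = [TimeHistogram(axis, np.full(axis.n_bins, 2.0), 30.0)
            for _ in range(5)]
    merged = merge_segments(segs)
    assert merged.total_counts == pytest.approx(10.0 * axis.n_bins)
    assert merged.acquisition_s == pytest.approx(150.0)
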