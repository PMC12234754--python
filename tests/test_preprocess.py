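"""The spectral correction chain, stage by stage."""

import numpy as np
import pytest

from oracles import als_oracle, loo_correlations

from ramantis.core import ShapeError, SiteMetadata, Spectrum, SpectrumSet, WavenumberAxis
from ramantis.preprocess import (
    ALSParams,
    CalibrationError,
    ConfigurationError,
    DespikeParams,
    NormalizationError,
    NumericDegeneracyError,
    PipelineStageError,
    QCParams,
    ResponseCurve,
    area_normalize,
    baseline_als,
    intensity_correct,
    preprocess_pipeline,
    qc_filter,
    remove_cosmic_spikes,
    subtract_dark,
)
from ramantis.simulate import (
    AcquisitionModel,
    BaselineFamily,
    TissueModel,
    reconstruct_noiseless,
    simulate_site,
)
from ramantis.workflows import calibration_inputs, process_site

from conftest import make_spectrum


class TestSubtractDark:
    def test_elementwise_subtraction(self):
        raw = make_spectrum([110, 120, 130, 140, 150, 160, 170, 180])
        dark = make_spectrum([10, 20, 30, 40, 50, 60, 70, 80])
        out = subtract_dark(raw, dark)
        np.testing.assert_array_equal(out.intensities, [100] * 8)

    def test_identical_inputs_give_zero(self):
        raw = make_spectrum(np.arange(8.0) + 100)
        out = subtract_dark(raw, raw)
        np.testing.assert_array_equal(out.intensities, np.zeros(8))

    def test_negative_channels_preserved(self):
        raw = make_spectrum([100, 100, 100, 100, 100, 100, 100, 100])
        dark = make_spectrum([10, 10, 10, 150, 10, 10, 10, 10])
        out = subtract_dark(raw, dark)
        assert out.intensities[3] == -50  # no clipping

    def test_axis_mismatch(self):
        raw = make_spectrum(np.ones(8))
        dark = make_spectrum(np.ones(8), lo=600.0)
        with pytest.raises(ShapeError):
            subtract_dark(raw, dark)


class TestDespike:
    def test_single_spike_on_flat_restored_by_interpolation(self):
        y = np.full(64, 100.0)
        y[30] = 10000.0
        out, mask = remove_cosmic_spikes(make_spectrum(y))
        assert list(np.flatnonzero(mask)) == [30]
        # oracle: direct neighbour interpolation on a flat trace
        assert out.intensities[30] == 100.0
        np.testing.assert_array_equal(out.intensities[~mask], y[~mask])

    def test_quiet_spectrum_unchanged(self):
        rng = np.random.default_rng(0)
        y = 100 + rng.normal(0, 1, 128)
        s = make_spectrum(y)
        out, mask = remove_cosmic_spikes(s, DespikeParams(z_thresh=8))
        assert mask.sum() == 0
        np.testing.assert_array_equal(out.intensities, y)

    def test_band_of_full_width_six_channels_not_flagged(self):
        # a Raman band (FWHM 6 channels) rises and falls over more than
        # max_width channels: the entry difference has no opposite-signed
        # exit within reach, and near-apex differences continue their
        # flanks' slope, so nothing is flagged
        rng = np.random.default_rng(1)
        n = 64
        idx = np.arange(n)
        band = 120.0 * np.exp(-(((idx - 32) / (6 / 2.355)) ** 2) / 2)
        y = 100.0 + rng.normal(0, 1, n) + band
        out, mask = remove_cosmic_spikes(make_spectrum(y),
                                         DespikeParams(z_thresh=8, max_width=3))
        assert mask.sum() == 0
        np.testing.assert_array_equal(out.intensities, y)

    def test_negative_spike_flagged(self):
        rng = np.random.default_rng(2)
        y = 500 + rng.normal(0, 2, 64)
        y[20] = -3000.0
        _, mask = remove_cosmic_spikes(make_spectrum(y))
        assert list(np.flatnonzero(mask)) == [20]

    def test_all_constant_spectrum_empty_mask(self):
        out, mask = remove_cosmic_spikes(make_spectrum(np.full(32, 7.0)))
        assert mask.sum() == 0

    def test_widespread_zero_mad_degenerate(self):
        # >25% of first differences depart from the median while the MAD
        # collapses to zero: no meaningful robust scale exists
        d = np.zeros(100)
        d[:35] = 100.0 * (-1.0) ** np.arange(35)
        y = np.concatenate([[500.0], 500.0 + np.cumsum(d)])
        with pytest.raises(NumericDegeneracyError):
            remove_cosmic_spikes(make_spectrum(y, step=5.0))

    def test_unflagged_channels_bitwise_identical(self):
        rng = np.random.default_rng(3)
        y = 1000 + 50 * np.sin(np.arange(256) / 10) + rng.normal(0, 5, 256)
        for c in (40, 41, 130):
            y[c] += 20000
        out, mask = remove_cosmic_spikes(make_spectrum(y))
        np.testing.assert_array_equal(out.intensities[~mask], y[~mask])
        assert {40, 41, 130} <= set(np.flatnonzero(mask))


class TestIntensityCorrect:
    def _curves(self, n=64):
        ax = WavenumberAxis(500 + 10.0 * np.arange(n))
        cert = ResponseCurve(ax, 1.0 + 0.5 * np.sin(ax.values / 300),
                             source="certified_polynomial")
        return ax, cert

    def test_identity_when_measured_equals_certified(self):
        ax, cert = self._curves()
        s = Spectrum(ax, 100 + np.arange(64.0))
        measured = Spectrum(ax, cert.relative_sensitivity.copy())
        out = intensity_correct(s, measured, cert)
        np.testing.assert_allclose(out.intensities, s.intensities, rtol=1e-12)

    def test_half_measured_doubles_intensities(self):
        ax, cert = self._curves()
        s = Spectrum(ax, np.full(64, 10.0))
        measured = Spectrum(ax, 0.5 * cert.relative_sensitivity)
        out = intensity_correct(s, measured, cert)
        np.testing.assert_allclose(out.intensities, 20.0, rtol=1e-12)

    def test_zero_measured_channel_is_calibration_error(self):
        ax, cert = self._curves()
        s = Spectrum(ax, np.ones(64))
        bad = cert.relative_sensitivity.copy()
        bad[17] = 0.0
        with pytest.raises(CalibrationError, match="17"):
            intensity_correct(s, Spectrum(ax, bad), cert)

    def test_inverse_roles_restore_input(self):
        ax, cert = self._curves()
        rng = np.random.default_rng(4)
        s = Spectrum(ax, rng.uniform(10, 100, 64))
        measured = Spectrum(ax, rng.uniform(0.5, 2.0, 64))
        fwd = intensity_correct(s, measured, cert)
        inv_cert = ResponseCurve(ax, measured.intensities, source="measured_standard")
        back = intensity_correct(fwd, Spectrum(ax, cert.relative_sensitivity),
                                 inv_cert)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-9)


class TestBaselineALS:
    def test_zero_spectrum_gives_zero_baseline(self, axis):
        s = Spectrum(axis, np.zeros(len(axis)))
        corrected, baseline = baseline_als(s)
        np.testing.assert_allclose(baseline.intensities, 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected.intensities, 0.0, atol=1e-12)

    def test_quadratic_background_removed(self, axis):
        u = np.linspace(0, 1, len(axis))
        bg = 1000 * (1 + 2 * u - 1.5 * u**2)
        corrected, _ = baseline_als(Spectrum(axis, bg))
        rms = np.sqrt(np.mean(corrected.intensities**2))
        assert rms < 0.01 * 1000

    def test_band_on_offset_recovered(self, axis):
        # one Gaussian band (h=500) on constant offset 200
        h, c, offset = 500.0, 1500.0, 200.0
        y = h * np.exp(-(((axis.values - c) / 30) ** 2)) + offset
        corrected, baseline = baseline_als(Spectrum(axis, y))
        peak = corrected.intensities[np.argmin(np.abs(axis.values - c))]
        assert abs(peak - h) / h < 0.05
        away = np.abs(axis.values - c) > 200
        assert np.max(np.abs(baseline.intensities[away] - offset)) / offset < 0.02

    def test_matches_dense_oracle(self, axis):
        rng = np.random.default_rng(5)
        n = 256
        ax = WavenumberAxis(np.linspace(500, 3300, n))
        u = np.linspace(0, 1, n)
        params = ALSParams()
        for _ in range(3):
            y = (rng.uniform(500, 2000) * np.exp(-u / rng.uniform(0.3, 0.8))
                 + rng.normal(0, 5, n))
            _, baseline = baseline_als(Spectrum(ax, y), params)
            z = als_oracle(y, params.lam, params.p, params.max_iter, params.tol)
            np.testing.assert_allclose(baseline.intensities, z, rtol=1e-6,
                                       atol=1e-6 * np.abs(z).max())

    def test_baseline_mostly_below_noisy_signal(self, axis):
        rng = np.random.default_rng(6)
        u = np.linspace(0, 1, len(axis))
        bg = 2500 * np.exp(-2 * u) + 300
        bands = 400 * np.exp(-(((axis.values - 1300) / 25) ** 2)) \
            + 300 * np.exp(-(((axis.values - 2900) / 25) ** 2))
        params = ALSParams()
        for _ in range(3):
            y = bg + bands + rng.normal(0, 40, len(axis))
            _, baseline = baseline_als(Spectrum(axis, y), params)
            frac_below = np.mean(baseline.intensities <= y)
            assert frac_below >= 1 - params.p - 0.05

    def test_nonconvergence_flagged_not_fatal(self, axis):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 1000, len(axis))
        with pytest.warns(RuntimeWarning):
            corrected, _ = baseline_als(Spectrum(axis, y),
                                        ALSParams(max_iter=1, tol=1e-12))
        assert len(corrected) == len(axis)


class TestQCFilter:
    def _site(self, mat):
        meta = SiteMetadata("P1", "larynx", "tumor")
        ax = WavenumberAxis(500 + 10.0 * np.arange(mat.shape[1]))
        return SpectrumSet(meta, [Spectrum(ax, row) for row in mat])

    def test_identical_copies_all_kept(self):
        row = np.sin(np.arange(64) / 5) + 2
        kept, rejected, scores = qc_filter(self._site(np.tile(row, (10, 1))))
        np.testing.assert_allclose(scores, 1.0)
        assert len(kept) == 10 and len(rejected) == 0

    def test_white_noise_trace_rejected_among_templates(self):
        rng = np.random.default_rng(8)
        template = 100 * np.exp(-(((np.arange(128) - 60) / 8.0) ** 2)) + 10
        mat = np.tile(template, (10, 1))
        mat[7] = rng.normal(0, 30, 128)
        kept, rejected, scores = qc_filter(self._site(mat),
                                           QCParams(min_correlation=0.8))
        np.testing.assert_allclose(scores, loo_correlations(mat), atol=1e-12)
        assert len(rejected) == 1
        assert scores[7] < 0.8
        assert all(s >= 0.8 for i, s in enumerate(scores) if i != 7)

    def test_singleton_passes_with_score_one(self):
        kept, rejected, scores = qc_filter(self._site(np.ones((1, 64))))
        assert len(kept) == 1 and len(rejected) == 0
        assert scores.tolist() == [1.0]

    def test_zero_variance_trace_scores_zero(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(100, 10, (5, 64))
        mat[2] = 42.0  # flat trace
        _, rejected, scores = qc_filter(self._site(mat),
                                        QCParams(min_correlation=0.1))
        assert scores[2] == 0.0
        assert any(np.array_equal(s.intensities, mat[2]) for s in rejected.spectra)

    def test_empty_set_rejected(self):
        meta = SiteMetadata("P1", "larynx", "tumor")
        with pytest.raises(ValueError):
            qc_filter(SpectrumSet(meta, []))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        base = 50 * np.exp(-(((np.arange(96) - 40) / 6.0) ** 2))
        mat = base + rng.normal(0, 3, (8, 96))
        perm = rng.permutation(8)
        _, _, scores = qc_filter(self._site(mat))
        _, _, scores_p = qc_filter(self._site(mat[perm]))
        np.testing.assert_allclose(scores_p, scores[perm], rtol=1e-12)


class TestAreaNormalize:
    def test_unit_integral(self):
        rng = np.random.default_rng(11)
        s = make_spectrum(rng.uniform(1, 10, 128))
        out = area_normalize(s)
        area = np.trapezoid(out.intensities, out.axis.values)
        assert abs(area - 1.0) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(1, 5, 64)
        a = area_normalize(make_spectrum(y))
        b = area_normalize(make_spectrum(3.7 * y))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_constant_spectrum_closed_form(self):
        # constant 5 over a span of width W normalizes to 1/W
        s = make_spectrum(np.full(101, 5.0), lo=1000.0, step=10.0)  # W = 1000
        out = area_normalize(s)
        np.testing.assert_allclose(out.intensities, 1.0 / 1000.0, rtol=1e-12)

    def test_nonpositive_integral_raises(self):
        s = make_spectrum(np.full(16, -1.0))
        with pytest.raises(NormalizationError):
            area_normalize(s)

    def test_window_restriction(self):
        s = make_spectrum(np.full(101, 2.0), lo=500.0, step=10.0)
        out = area_normalize(s, window=(600.0, 800.0))
        x, y = out.axis.values, out.intensities
        mask = (x >= 600) & (x <= 800)
        assert abs(np.trapezoid(y[mask], x[mask]) - 1.0) < 1e-9


class TestPipeline:
    def _clean_models(self):
        quiet = BaselineFamily(exp_amp=(0, 0), exp_tau=(1000, 1000),
                               c0=(0, 0), c1=(0, 0), c2=(0, 0))
        tissue = TissueModel(baseline=quiet)
        axis = WavenumberAxis.default()
        flat = ResponseCurve(axis, np.ones(len(axis)))
        acq = AcquisitionModel(response=flat, read_noise_sd=0.0,
                               shot_noise=False, spike_rate=0.0,
                               spectra_per_site=(3, 3))
        return tissue, acq

    def test_noiseless_site_reduces_to_normalized_band_model(self, healthy_meta):
        # with noise, spikes, response and fluorescence all switched off,
        # dark subtraction, despiking and intensity calibration are exact
        # identities; the only transformation left is ALS (which removes
        # the smooth pedestal formed by overlapping Lorentzian tails) and
        # area normalization, both reproduced here independently
        tissue, acq = self._clean_models()
        site, manifest = simulate_site(tissue, acq, healthy_meta, 21)
        res = process_site(site, acq)
        assert len(res.processed) == 3
        assert all(m.sum() == 0 for m in res.spike_masks)
        params = ALSParams()
        x = acq.axis.values
        for s, entry in zip(res.processed.spectra, manifest["entries"]):
            model = reconstruct_noiseless(tissue, acq, entry) - acq.dark_offset
            expected = model - als_oracle(model, params.lam, params.p,
                                          params.max_iter, params.tol)
            expected = expected / np.trapezoid(expected, x)
            np.testing.assert_allclose(s.intensities, expected, rtol=1e-6,
                                       atol=1e-6 * np.abs(expected).max())
        # the shape itself is still recognizably the band model: every
        # planted center remains the local maximum of its neighbourhood
        mean = res.processed.spectra[0]
        for band in tissue.bands:
            near = np.abs(x - band.center) <= 12
            peak_nu = x[near][np.argmax(mean.intensities[near])]
            assert abs(peak_nu - band.center) <= 2 * mean.axis.spacing

    def test_planted_spikes_flagged_and_bands_preserved(self, tissue, healthy_meta):
        acq = AcquisitionModel(spike_rate=2.0, spectra_per_site=(12, 12))
        site, manifest = simulate_site(tissue, acq, healthy_meta, 33)
        res = process_site(site, acq)
        for mask, entry in zip(res.spike_masks, manifest["entries"]):
            assert set(entry["spike_channels"]) <= set(np.flatnonzero(mask))
        from ramantis.cohort import detect_peaks, group_mean_sd

        mean, _ = group_mean_sd(res.processed.spectra)
        floor = 0.05 * (mean.intensities.max() - mean.intensities.min())
        peaks = detect_peaks(mean, floor, 20.0)
        spacing = mean.axis.spacing
        for planted in (1003.0, 1448.0, 2920.0):
            nearest = min(abs(p.center - planted) for p in peaks)
            assert nearest < spacing  # center preserved within one channel

    def test_missing_dark_is_configuration_error(self, tissue, acq, healthy_meta):
        site, _ = simulate_site(tissue, acq, healthy_meta, 5)
        _, standard, certified = calibration_inputs(acq)
        with pytest.raises(ConfigurationError):
            preprocess_pipeline(site, None, standard, certified)

    def test_stage_errors_carry_stage_name(self, tissue, acq, healthy_meta):
        site, _ = simulate_site(tissue, acq, healthy_meta, 5)
        dark, standard, certified = calibration_inputs(acq)
        bad_standard = Spectrum(standard.axis,
                                np.where(np.arange(1024) == 7, 0.0,
                                         standard.intensities))
        with pytest.raises(PipelineStageError) as err:
            preprocess_pipeline(site, dark, bad_standard, certified)
        assert err.value.stage == "intensity_correct"
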