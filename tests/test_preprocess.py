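"""Preprocessing-chain tests against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import evraman as ev
from evraman.containers import AxisError, ResponseCurve
from evraman.preprocess import (DegenerateSpectrumError, PipelineConfig,
                                WhittakerConvergenceError,
                                apply_response_correction, crop_fingerprint,
                                normalize_auc, preprocess_pipeline,
                                remove_cosmic_spikes, savgol_smooth,
                                subtract_background, threshold_filter,
                                whittaker_baseline)


def _spectrum(wn, y, **meta):
    return ev.RamanSpectrum(np.arange(len(wn)), wn, y, dict(meta, id="s0"))


@pytest.fixture()
def clean_noisy_spectrum(axis, truths):
    """A realistic spike-free acquisition (bands + baseline + shot noise)."""
    profile = ev.ClassProfile("x", (0.3, 0.2, 0.35, 0.15), spike_rate=0.0)
    return ev.generate_ev_spectrum(profile, truths, axis, seed=404)


# -- cosmic spikes -----------------------------------------------------------

class TestSpikeRemoval:
    def test_clean_spectrum_unchanged_no_flags(self, clean_noisy_spectrum):
        out, flagged = remove_cosmic_spikes(clean_noisy_spectrum)
        assert flagged == []
        np.testing.assert_array_equal(out.intensities,
                                      clean_noisy_spectrum.intensities)

    def test_single_spike_flagged_and_recovered(self, clean_noisy_spectrum):
        y = clean_noisy_spectrum.intensities
        sigma = np.std(np.diff(y)) / np.sqrt(2)  # local noise scale
        k = 500
        spiked = y.copy()
        spiked[k] += 50 * sigma
        out, flagged = remove_cosmic_spikes(
            clean_noisy_spectrum.with_intensities(spiked))
        assert flagged == [k]
        assert abs(out.intensities[k] - y[k]) <= 3 * sigma

    def test_adjacent_spikes_both_interpolated(self, clean_noisy_spectrum):
        y = clean_noisy_spectrum.intensities
        sigma = np.std(np.diff(y)) / np.sqrt(2)
        spiked = y.copy()
        spiked[300] += 60 * sigma
        spiked[301] += 45 * sigma
        out, flagged = remove_cosmic_spikes(
            clean_noisy_spectrum.with_intensities(spiked))
        assert set(flagged) >= {300, 301}
        for k in (300, 301):
            assert abs(out.intensities[k] - y[k]) <= 4 * sigma

    def test_unflagged_channels_never_altered(self, clean_noisy_spectrum):
        y = clean_noisy_spectrum.intensities
        spiked = y.copy()
        spiked[700] += 1e5
        out, flagged = remove_cosmic_spikes(
            clean_noisy_spectrum.with_intensities(spiked))
        keep = np.ones(len(y), dtype=bool)
        keep[flagged] = False
        np.testing.assert_array_equal(out.intensities[keep], spiked[keep])

    def test_all_channels_flagged_raises(self, clean_noisy_spectrum):
        # negative thresholds force every channel past both criteria
        cfg = PipelineConfig(spike_amp_threshold=-1.0,
                             spike_d2_threshold=-1.0)
        with pytest.raises(DegenerateSpectrumError):
            remove_cosmic_spikes(clean_noisy_spectrum, cfg)


# -- response correction ------------------------------------------------------

class TestResponseCorrection:
    def test_unity_factor_is_identity(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        curve = ResponseCurve(s.wavenumbers, np.ones(s.n_channels))
        out = apply_response_correction(s, curve)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_constant_factor_two_doubles(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        curve = ResponseCurve(s.wavenumbers, np.full(s.n_channels, 2.0))
        out = apply_response_correction(s, curve)
        np.testing.assert_allclose(out.intensities, 2 * s.intensities)

    def test_linear_ramp_matches_elementwise_oracle(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        factors = np.linspace(0.7, 1.3, s.n_channels)
        curve = ResponseCurve(s.wavenumbers, factors)
        out = apply_response_correction(s, curve)
        expected = np.array([s.intensities[i] * factors[i]
                             for i in range(s.n_channels)])
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-12)

    def test_nonpositive_factor_rejected(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        with pytest.raises(ValueError):
            ResponseCurve(s.wavenumbers, np.full(s.n_channels, -1.0))

    def test_curve_not_covering_range_rejected(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        curve = ResponseCurve(s.wavenumbers[10:], np.ones(s.n_channels - 10))
        with pytest.raises(AxisError):
            apply_response_correction(s, curve)


# -- threshold filter ---------------------------------------------------------

class TestThresholdFilter:
    def test_disabled_is_identity(self, two_class_batches):
        m = two_class_batches["raw1"]
        out, rejected = threshold_filter(m, PipelineConfig())
        assert rejected == []
        assert out.n_spectra == m.n_spectra

    def test_counts_below_minimum(self, axis):
        rng = np.random.default_rng(0)
        wn = axis.wavenumbers()
        X = rng.uniform(10, 20, size=(10, len(wn)))
        X[[2, 5, 7]] *= 0.01  # background-only traps
        m = ev.SpectraMatrix(wn, X, {"id": [f"s{i}" for i in range(10)]})
        out, rejected = threshold_filter(
            m, PipelineConfig(min_intensity=5.0))
        assert out.n_spectra == 7
        assert sorted(rejected) == ["s2", "s5", "s7"]

    def test_matches_exhaustive_per_row_oracle(self, axis):
        rng = np.random.default_rng(1)
        wn = axis.wavenumbers()
        X = rng.uniform(0, 100, size=(40, len(wn)))
        m = ev.SpectraMatrix(wn, X, {"id": [f"s{i}" for i in range(40)]})
        cfg = PipelineConfig(min_intensity=60.0, max_intensity=99.0)
        out, rejected = threshold_filter(m, cfg)
        expected_keep = [i for i in range(40)
                         if 60.0 <= X[i].max() <= 99.0]
        assert list(out.ids) == [f"s{i}" for i in expected_keep]


# -- PBS subtraction ----------------------------------------------------------

class TestBackgroundSubtraction:
    def test_residual_is_five_percent_of_mean(self, pbs_reference):
        mean = pbs_reference.intensities.mean(axis=0)
        s = _spectrum(pbs_reference.wavenumbers, mean)
        out = subtract_background(s, pbs_reference,
                                  PipelineConfig(pbs_fraction=0.95))
        np.testing.assert_allclose(out.intensities, 0.05 * mean, atol=1e-9)

    def test_full_fraction_zero_residual(self, pbs_reference):
        mean = pbs_reference.intensities.mean(axis=0)
        s = _spectrum(pbs_reference.wavenumbers, mean)
        out = subtract_background(s, pbs_reference,
                                  PipelineConfig(pbs_fraction=1.0))
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_matches_loop_oracle(self, pbs_reference):
        rng = np.random.default_rng(3)
        wn = pbs_reference.wavenumbers
        y = rng.uniform(0, 500, len(wn))
        out = subtract_background(_spectrum(wn, y), pbs_reference,
                                  PipelineConfig(pbs_fraction=0.95))
        expected = np.array([
            y[i] - 0.95 * pbs_reference.intensities[:, i].mean()
            for i in range(len(wn))
        ])
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-12)

    def test_axis_mismatch_rejected(self, pbs_reference):
        wn = pbs_reference.wavenumbers
        s = _spectrum(wn + 1.0, np.ones(len(wn)))
        with pytest.raises(AxisError):
            subtract_background(s, pbs_reference, PipelineConfig())


# -- crop ---------------------------------------------------------------------

class TestCropFingerprint:
    def test_retained_count_matches_exhaustive_count(self):
        wn = np.linspace(500, 2000, 700)
        s = _spectrum(wn, np.ones(700))
        out = crop_fingerprint(s, PipelineConfig(crop=(600.0, 1800.0)))
        expected = sum(1 for w in wn if 600.0 <= w <= 1800.0)
        assert out.n_channels == expected

    def test_full_cover_is_identity(self, clean_noisy_spectrum):
        s = clean_noisy_spectrum
        out = crop_fingerprint(s, PipelineConfig(crop=(0.0, 1e4)))
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_disjoint_crop_raises(self, clean_noisy_spectrum):
        with pytest.raises(DegenerateSpectrumError):
            crop_fingerprint(clean_noisy_spectrum,
                             PipelineConfig(crop=(3000.0, 3100.0)))


# -- Whittaker baseline -------------------------------------------------------

def _whittaker_dense_oracle(y, lam, p, max_iter=50):
    """Dense linear-solve replication of the asymmetric-weight iteration."""
    n = len(y)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i:i + 3] = [1.0, -2.0, 1.0]
    w = np.ones(n)
    seen = {w.tobytes()}
    for _ in range(max_iter):
        A = np.diag(w) + lam * D.T @ D
        z = np.linalg.solve(A, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w) or w_new.tobytes() in seen:
            return z
        seen.add(w_new.tobytes())
        w = w_new
    raise RuntimeError("oracle did not converge")


class TestWhittakerBaseline:
    def test_tiny_lambda_baseline_equals_input(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 10, 80)
        z, corrected = whittaker_baseline(y, lam=1e-12, p=1e-4)
        np.testing.assert_allclose(z, y, atol=1e-6)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-6)

    @pytest.mark.parametrize("lam", [1e0, 1e4, 1e6])
    def test_constant_input_exact_minimizer(self, lam):
        y = np.full(60, 7.5)
        z, corrected = whittaker_baseline(y, lam=lam, p=1e-4)
        # tolerance follows the conditioning of W + lam D'D as lam grows
        np.testing.assert_allclose(z, y, atol=1e-6)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-6)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0, 100, 50) + np.linspace(0, 50, 50)
        z, _ = whittaker_baseline(y, lam=1e4, p=1e-4)
        z_oracle = _whittaker_dense_oracle(y, 1e4, 1e-4)
        np.testing.assert_allclose(z, z_oracle, rtol=1e-8)

    def test_large_lambda_flattens_curvature(self):
        """As lam grows the baseline approaches the global linear trend."""
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 10, 200) + np.linspace(0, 5, 200)
        d2 = {}
        for lam in (1e2, 1e6, 1e12):
            z, _ = whittaker_baseline(y, lam=lam, p=0.5)
            d2[lam] = np.abs(np.diff(z, 2)).max()
        assert d2[1e6] < d2[1e2]
        assert d2[1e12] < 1e-6

    def test_nonconvergence_reports_iterations(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(120)
        with pytest.raises(WhittakerConvergenceError) as err:
            whittaker_baseline(y, lam=10.0, p=0.3, max_iter=1)
        assert err.value.iterations == 1

    def test_invalid_parameters_rejected(self):
        y = np.ones(10)
        with pytest.raises(ValueError):
            whittaker_baseline(y, lam=-1.0)
        with pytest.raises(ValueError):
            whittaker_baseline(y, p=1.5)


# -- Savitzky-Golay -----------------------------------------------------------

def _savgol_window_oracle(y, frame, order):
    """Per-window least-squares polynomial fit, shrink-window at edges."""
    n = len(y)
    half = frame // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        k = min(order, 2 * h)
        idx = np.arange(i - h, i + h + 1)
        if len(idx) <= k:
            out[i] = y[i]
            continue
        coeffs = np.polyfit(idx - i, y[idx], k)
        out[i] = coeffs[-1]
    return out


class TestSavgolSmooth:
    def test_linear_input_unchanged(self):
        y = 3.0 * np.arange(50.0) + 2.0
        out = savgol_smooth(y, PipelineConfig(sg_order=1, sg_frame=7))
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_constant_input_unchanged_everywhere(self):
        y = np.full(30, 4.2)
        out = savgol_smooth(y, PipelineConfig(sg_order=1, sg_frame=7))
        np.testing.assert_allclose(out, y, atol=1e-12)

    def test_matches_windowed_regression_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(64)
        out = savgol_smooth(y, PipelineConfig(sg_order=1, sg_frame=7))
        np.testing.assert_allclose(out, _savgol_window_oracle(y, 7, 1),
                                   atol=1e-10)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(sg_frame=6)  # even
        with pytest.raises(ValueError):
            PipelineConfig(sg_frame=3, sg_order=5)  # frame <= order
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(5), PipelineConfig(sg_frame=7))  # > channels


# -- normalization ------------------------------------------------------------

class TestNormalizeAUC:
    def test_constant_spectrum_closed_form(self):
        wn = np.linspace(600.0, 1800.0, 300)
        s = _spectrum(wn, np.full(300, 5.0))
        out = normalize_auc(s)
        np.testing.assert_allclose(out.intensities, 1.0 / 1200.0, rtol=1e-12)

    def test_idempotent(self, clean_noisy_spectrum):
        once = normalize_auc(clean_noisy_spectrum)
        twice = normalize_auc(once)
        np.testing.assert_allclose(twice.intensities, once.intensities,
                                   rtol=1e-12)

    def test_area_one_by_independent_trapezoid_oracle(self):
        rng = np.random.default_rng(6)
        wn = np.sort(rng.uniform(600, 1800, 200))
        s = _spectrum(wn, rng.uniform(1, 10, 200))
        out = normalize_auc(s)
        area = sum(
            0.5 * (out.intensities[i] + out.intensities[i + 1])
            * (wn[i + 1] - wn[i])
            for i in range(199)
        )
        assert area == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, k):
        wn = np.linspace(600.0, 1800.0, 128)
        y = np.abs(np.sin(wn / 50.0)) + 0.1
        a = normalize_auc(_spectrum(wn, y))
        b = normalize_auc(_spectrum(wn, k * y))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_nonpositive_area_rejected(self):
        wn = np.linspace(600, 700, 10)
        with pytest.raises(ValueError):
            normalize_auc(_spectrum(wn, -np.ones(10)))


# -- full pipeline ------------------------------------------------------------

class TestPipeline:
    def test_all_steps_disabled_is_identity(self, two_class_batches):
        m = two_class_batches["raw1"].select(np.arange(5))
        cfg = PipelineConfig(despike=False, crop=None, whittaker_lambda=None,
                            sg_frame=None, normalize=False)
        out, log = preprocess_pipeline(m, None, None, cfg)
        assert log["steps"] == []
        np.testing.assert_array_equal(out.intensities, m.intensities)

    def test_output_area_is_one(self, two_class_batches):
        proc = two_class_batches["proc1"]
        areas = np.trapezoid(proc.intensities, proc.wavenumbers, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_noise_free_mixture_recovers_generating_shape(self, axis, truths):
        """Noise-free convex mixtures pass through the chain nearly
        unchanged in shape (cosine >= 0.99 vs the normalized mixture)."""
        profile = ev.ClassProfile("x", (0.3, 0.2, 0.35, 0.15),
                                  weight_dispersion=np.inf, snr=np.inf,
                                  spike_rate=0.0)
        cfg = ev.SimConfig(classes=(profile,), n_per_class=3, seed=1,
                           baseline_amplitude=0.0, pbs_amplitude=0.0)
        m = ev.generate_dataset(cfg, truths)
        pbs = ev.generate_pbs_reference(axis, 50, 2, amplitude=0.0,
                                        noise_sigma=0.0)
        out, _ = preprocess_pipeline(m, pbs, None, PipelineConfig())
        wn0 = axis.wavenumbers()
        mask = (wn0 >= 600) & (wn0 <= 1800)
        mix = sum(w * t.spectrum for w, t in zip(profile.mean_weights, truths))
        mix = mix[mask]
        mix = mix / np.trapezoid(mix, out.wavenumbers)
        for row in out.intensities:
            cos = row @ mix / (np.linalg.norm(row) * np.linalg.norm(mix))
            assert cos >= 0.99

    def test_step_order_matters(self, clean_noisy_spectrum):
        """Whittaker-then-normalize differs from normalize-then-Whittaker."""
        from evraman.preprocess import whittaker_correct
        s = clean_noisy_spectrum
        a = normalize_auc(whittaker_correct(s))
        corrected = whittaker_correct(normalize_auc(s))
        assert not np.allclose(a.intensities, corrected.intensities,
                               rtol=1e-6)

    def test_missing_pbs_skips_subtraction(self, two_class_batches):
        m = two_class_batches["raw1"].select(np.arange(3))
        out, log = preprocess_pipeline(m, None, None, PipelineConfig())
        assert "subtract_background" not in log["steps"]
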