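"""Spectral estimation: periodograms, normalization, line fits, form factor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qusresponse as q
from qusresponse.qus_spectral import (
    DB_FLOOR,
    block_power_spectrum,
    estimate_bsc,
    fit_gaussian_form_factor,
    fit_spectral_params,
    normalize_spectrum,
)


def make_nps(values, freqs=None, depth=1.0):
    freqs = np.linspace(2.0, 10.0, 81) if freqs is None else freqs
    vals = np.broadcast_to(np.asarray(values, dtype=float), freqs.shape)
    return q.PowerSpectrum(freqs, vals.copy(), block_depth_cm=depth, kind="normalized")


class TestBlockPowerSpectrum:
    def test_tone_peaks_at_nearest_grid_frequency(self, pulse):
        t = np.arange(256) / pulse.sampling_frequency  # microseconds
        tone = np.cos(2 * np.pi * 6.0 * t)[None, :]
        ps = block_power_spectrum(tone, pulse)
        peak = ps.frequencies_mhz[np.argmax(ps.values_db)]
        df = ps.frequencies_mhz[1] - ps.frequencies_mhz[0]
        assert abs(peak - 6.0) <= df

    def test_zero_block_clamps_to_floor_and_fit_refuses(self, pulse):
        ps = block_power_spectrum(np.zeros((4, 64)), pulse)
        assert np.all(ps.values_db == DB_FLOOR)
        nps = q.PowerSpectrum(ps.frequencies_mhz, ps.values_db, kind="normalized")
        with pytest.raises(q.ValidationError):
            fit_spectral_params(nps, pulse)

    def test_duplicated_scan_line_leaves_average_unchanged(self, pulse, homogeneous_frame):
        line = homogeneous_frame.samples[:1, 100:228]
        single = block_power_spectrum(line, pulse)
        doubled = block_power_spectrum(np.vstack([line, line]), pulse)
        np.testing.assert_allclose(doubled.values_db, single.values_db, rtol=0, atol=1e-9)

    def test_empty_block_rejected(self, pulse):
        with pytest.raises(q.ValidationError):
            block_power_spectrum(np.zeros((1, 8)), pulse)


class TestNormalization:
    def test_self_normalization_is_identically_zero(self, pulse, homogeneous_frame):
        ps = block_power_spectrum(homogeneous_frame.samples[:, 100:228], pulse)
        nps = normalize_spectrum(ps, ps, depth_cm=1.5, alpha_sample_db_mhz_cm=0.7,
                                 alpha_ref_db_mhz_cm=0.7)
        assert np.all(nps.values_db == 0.0)
        sp = fit_spectral_params(nps, pulse)
        assert sp.ss_db_per_mhz == 0.0 and sp.si_db == 0.0 and sp.mbf_db == 0.0

    def test_attenuation_compensation_is_4_alpha_f_d(self):
        freqs = np.linspace(3.0, 8.0, 51)
        ps = q.PowerSpectrum(freqs, np.zeros_like(freqs), kind="raw")
        nps = normalize_spectrum(ps, ps, depth_cm=1.0, alpha_sample_db_mhz_cm=0.5,
                                 alpha_ref_db_mhz_cm=0.0)
        at6 = nps.values_db[np.argmin(np.abs(freqs - 6.0))]
        assert at6 == pytest.approx(12.0, abs=1e-12)

    def test_grid_mismatch_raises(self):
        a = q.PowerSpectrum(np.linspace(3, 8, 11), np.zeros(11))
        b = q.PowerSpectrum(np.linspace(3, 9, 11), np.zeros(11))
        with pytest.raises(q.AlignmentError):
            normalize_spectrum(a, b, 1.0, 0.5, 0.5)

    def test_compensated_spectrum_flat_against_zero_attenuation_phantom(self, pulse):
        # sample medium shares the phantom's scatterers but attenuates at
        # 0.8 dB/MHz.cm; after compensation the normalized spectrum must be
        # flat over the band (averaged over frames to tame speckle noise)
        geom = q.FrameGeometry(n_lines=60, line_pitch_mm=0.1, depth_start_mm=8, depth_end_mm=14)
        phantom0 = q.PhantomSpec(attenuation_db_mhz_cm=0.0, sound_speed=pulse.sound_speed)
        alpha = 0.8
        gate = slice(100, 204)  # thin 2 mm gate: compensation depth well-defined
        rng = np.random.default_rng(8)
        acc_s, acc_r = None, None
        for _ in range(20):
            fieldspec = q.homogeneous_field(
                geom, phantom0.bead_density_per_mm2, phantom0.bead_radius_um, 1.0, rng
            )
            sample = q.simulate_rf_frame(
                fieldspec, pulse, alpha, geom, seed=int(rng.integers(2**31)), snr_db=None
            )
            ref = q.make_reference_frame(phantom0, pulse, geom, seed=int(rng.integers(2**31)))
            ps = block_power_spectrum(sample.samples[:, gate], pulse)
            pr = block_power_spectrum(ref.samples[:, gate], pulse)
            lin_s, lin_r = 10 ** (ps.values_db / 10), 10 ** (pr.values_db / 10)
            acc_s = lin_s if acc_s is None else acc_s + lin_s
            acc_r = lin_r if acc_r is None else acc_r + lin_r
            freqs = ps.frequencies_mhz
        depth_cm = sample.sample_depth_mm((gate.start + gate.stop) / 2) / 10
        mean_s = q.PowerSpectrum(freqs, 10 * np.log10(acc_s), kind="raw")
        mean_r = q.PowerSpectrum(freqs, 10 * np.log10(acc_r), kind="raw")
        nps = normalize_spectrum(mean_s, mean_r, depth_cm, alpha, 0.0)
        band = nps.band(pulse.band_low, pulse.band_high)
        assert np.all(np.abs(nps.values_db[band]) <= 1.0)


class TestSpectralFit:
    def test_exact_line_recovers_slope_intercept_midband(self, pulse):
        nps = make_nps(0.0)
        nps.values_db = 2.0 * nps.frequencies_mhz + 3.0
        sp = fit_spectral_params(nps, pulse)
        assert sp.ss_db_per_mhz == pytest.approx(2.0, abs=1e-10)
        assert sp.si_db == pytest.approx(3.0, abs=1e-9)
        assert sp.mbf_db == pytest.approx(15.0, abs=1e-9)

    def test_flat_spectrum_gives_zero_slope(self, pulse):
        sp = fit_spectral_params(make_nps(7.25), pulse)
        assert sp.ss_db_per_mhz == pytest.approx(0.0, abs=1e-12)
        assert sp.si_db == pytest.approx(7.25) and sp.mbf_db == pytest.approx(7.25)

    def test_midband_identity_holds_for_fitted_blocks(self, pulse, homogeneous_maps):
        mbf, ss, si = (homogeneous_maps[p] for p in ("MBF", "SS", "SI"))
        v = mbf.valid
        np.testing.assert_allclose(
            mbf.values[v], si.values[v] + ss.values[v] * pulse.center_frequency, rtol=0, atol=1e-9
        )

    def test_noisy_line_slope_unbiased_within_two_standard_errors(self, pulse):
        # closed-form OLS oracle: var(slope) = sigma^2 / sum((f - fbar)^2)
        rng = np.random.default_rng(12)
        freqs = np.linspace(3.0, 8.0, 26)
        sigma, true_slope = 1.0, -0.8
        inband = np.ones_like(freqs, dtype=bool)
        slopes = []
        for _ in range(100):
            nps = q.PowerSpectrum(
                freqs, true_slope * freqs + 4.0 + rng.normal(0, sigma, freqs.size), kind="normalized"
            )
            slopes.append(fit_spectral_params(nps, pulse).ss_db_per_mhz)
        se_mean = sigma / np.sqrt(np.sum((freqs - freqs.mean()) ** 2)) / np.sqrt(100)
        assert abs(np.mean(slopes) - true_slope) < 2 * se_mean

    def test_too_few_inband_points_raises(self, pulse):
        freqs = np.array([1.0, 5.0, 6.0, 12.0])
        nps = q.PowerSpectrum(freqs, np.zeros(4), kind="normalized")
        with pytest.raises(q.InsufficientSupportError):
            fit_spectral_params(nps, pulse)


class TestBSC:
    def test_zero_db_normalization_returns_reference_exactly(self):
        freqs = np.linspace(3, 8, 26)
        ref = q.BSCCurve(freqs, q.analytic_bsc(freqs, 12.0, 10.0))
        nps = make_nps(0.0, freqs)
        out = estimate_bsc(nps, ref)
        np.testing.assert_array_equal(out.values, ref.values)

    def test_ten_db_scales_reference_by_decade(self):
        freqs = np.linspace(3, 8, 26)
        ref = q.BSCCurve(freqs, q.analytic_bsc(freqs, 12.0, 10.0))
        out = estimate_bsc(make_nps(10.0, freqs), ref)
        np.testing.assert_allclose(out.values, 10.0 * ref.values, rtol=1e-12)

    def test_simulated_block_bsc_within_3db_of_truth(self, pulse, homogeneous_frame,
                                                     reference_frame, phantom):
        # whole-frame spectra: ratio to analytic truth within +-3 dB in-band
        s0, s1 = 100, 356
        ps = block_power_spectrum(homogeneous_frame.samples[:, s0:s1], pulse)
        pr = block_power_spectrum(reference_frame.samples[:, s0:s1], pulse)
        depth_cm = homogeneous_frame.sample_depth_mm((s0 + s1) / 2) / 10
        scale = phantom.sound_speed / pulse.sound_speed
        pr.values_db = pr.values_db + 4 * phantom.attenuation_db_mhz_cm * pr.frequencies_mhz * (scale - 1) * depth_cm
        nps = normalize_spectrum(ps, pr, depth_cm, 1.0, phantom.attenuation_db_mhz_cm)
        ref_bsc = q.BSCCurve(
            nps.frequencies_mhz,
            q.analytic_bsc(nps.frequencies_mhz, phantom.bead_radius_um,
                           phantom.bead_density_per_mm2, sound_speed=phantom.sound_speed),
        )
        bsc = estimate_bsc(nps, ref_bsc)
        band = nps.band(pulse.band_low, pulse.band_high)
        truth = q.analytic_bsc(nps.frequencies_mhz, 28.0, 8.0)
        ratio_db = 10 * np.log10(bsc.values[band] / truth[band])
        assert np.all(np.abs(ratio_db) <= 3.0)


class TestFormFactorFit:
    def test_exact_model_refit_recovers_asd_to_machine_precision(self):
        freqs = np.linspace(3, 8, 26)
        bsc = q.BSCCurve(freqs, q.analytic_bsc(freqs, 25.0, 8.0))
        scat = fit_gaussian_form_factor(bsc, 1540.0)
        assert scat.asd_um == pytest.approx(50.0, rel=1e-12)

    def test_pure_f4_spectrum_has_no_identifiable_radius(self):
        freqs = np.linspace(3, 8, 26)
        bsc = q.BSCCurve(freqs, freqs**4)
        with pytest.raises(q.FitFailureError):
            fit_gaussian_form_factor(bsc, 1540.0)

    def test_noisy_model_median_asd_within_10_percent(self):
        from qusresponse.studies import asd_recovery

        out = asd_recovery(true_radius_um=25.0, noise_cv=0.05, n_replicates=200, seed=4)
        assert out["noise_free_relative_error"] < 1e-10
        assert out["median_noisy_relative_error_pct"] < 10.0

    def test_aac_tracks_density_exactly_in_the_model(self):
        freqs = np.linspace(3, 8, 26)
        a = fit_gaussian_form_factor(q.BSCCurve(freqs, q.analytic_bsc(freqs, 25.0, 5.0)), 1540.0)
        b = fit_gaussian_form_factor(q.BSCCurve(freqs, q.analytic_bsc(freqs, 25.0, 10.0)), 1540.0)
        assert b.aac_db - a.aac_db == pytest.approx(10 * np.log10(2.0), abs=1e-9)


def test_gain_invariance_of_spectral_parameters(pulse, homogeneous_frame, reference_frame):
    """Scaling the RF by g leaves SS unchanged, shifts SI/MBF by 20 log10 g
    and scales the BSC by g^2."""
    gain = 3.7
    s0, s1 = 120, 248
    ps1 = block_power_spectrum(homogeneous_frame.samples[:, s0:s1], pulse)
    ps2 = block_power_spectrum(gain * homogeneous_frame.samples[:, s0:s1], pulse)
    pr = block_power_spectrum(reference_frame.samples[:, s0:s1], pulse)
    nps1 = normalize_spectrum(ps1, pr, 1.3, 1.0, 0.576)
    nps2 = normalize_spectrum(ps2, pr, 1.3, 1.0, 0.576)
    sp1, sp2 = fit_spectral_params(nps1, pulse), fit_spectral_params(nps2, pulse)
    shift = 20 * np.log10(gain)
    assert sp2.ss_db_per_mhz == pytest.approx(sp1.ss_db_per_mhz, abs=1e-9)
    assert sp2.si_db - sp1.si_db == pytest.approx(shift, abs=1e-8)
    ref = q.BSCCurve(nps1.frequencies_mhz, q.analytic_bsc(nps1.frequencies_mhz, 12.0, 10.0))
    b1, b2 = estimate_bsc(nps1, ref), estimate_bsc(nps2, ref)
    np.testing.assert_allclose(b2.values, gain**2 * b1.values, rtol=1e-8)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    slope=st.floats(-3, 3, allow_nan=False),
    intercept=st.floats(-30, 30, allow_nan=False),
)
def test_linear_spectra_always_satisfy_midband_identity(slope, intercept):
    pulse = q.PulseSpec()
    freqs = np.linspace(3.0, 8.0, 21)
    nps = q.PowerSpectrum(freqs, slope * freqs + intercept, kind="normalized")
    sp = fit_spectral_params(nps, pulse)
    assert sp.mbf_db == pytest.approx(sp.si_db + sp.ss_db_per_mhz * 6.0, abs=1e-8)
    assert sp.ss_db_per_mhz == pytest.approx(slope, abs=1e-6)
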