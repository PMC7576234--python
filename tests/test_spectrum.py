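from dataclasses import replace

import numpy as np
import pytest

from nadscope.simulate import default_spectrum_truth, simulate_spectrum
from nadscope.spectrum import (
    Spectrum,
    align_to_pcr,
    baseline_correct,
    integrate_window,
    pcr_atp_ratio,
    phase_correct,
    read_spectrum,
    write_spectrum,
)


def lorentzian_spectrum(a=1.0, w=0.1, c=0.0, lo=-5.0, hi=5.0, n=20001):
    x = np.linspace(lo, hi, n)
    y = (a * w**2) / ((x - c) ** 2 + w**2)  # apex amplitude a
    return Spectrum(x, y)


class TestSpectrumContainer:
    def test_non_monotonic_axis_rejected(self):
        with pytest.raises(ValueError, match="monotonic"):
            Spectrum(np.array([0.0, 1.0, 0.5]), np.zeros(3))

    def test_descending_axis_normalized_to_ascending(self):
        s = Spectrum(np.array([2.0, 1.0, 0.0]), np.array([1.0, 2.0, 3.0]))
        assert np.all(np.diff(s.ppm) > 0)
        assert s.intensity[0] == 3.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(4.0), np.zeros(3))


class TestSpectrumIO:
    @pytest.mark.parametrize("fmt", ["2col", "3col"])
    def test_roundtrip(self, tmp_path, fmt):
        truth = default_spectrum_truth(snr=30.0, seed=5)
        spec, _ = simulate_spectrum(truth)
        path = tmp_path / "s.csv"
        write_spectrum(spec, path, fmt=fmt)
        back = read_spectrum(path)
        assert np.allclose(back.ppm, spec.ppm, atol=1e-6)
        assert np.allclose(back.intensity, spec.intensity, rtol=1e-6, atol=1e-8)
        assert back.is_complex == (fmt == "3col")


class TestPhaseCorrect:
    def test_zero_phase_is_identity(self):
        spec, _ = simulate_spectrum(default_spectrum_truth(snr=30.0, seed=1))
        out = phase_correct(spec, 0.0, 0.0)
        assert np.allclose(out.intensity, spec.intensity)

    def test_pi_rotation_inverts_absorptive_peak(self, full_noiseless):
        spec, _ = full_noiseless
        out = phase_correct(spec, phi0=np.pi)
        assert np.isclose(out.intensity.min(), -spec.intensity.max(), rtol=1e-10)

    def test_auto_recovers_injected_zero_order_phase(self):
        truth = default_spectrum_truth(snr=np.inf, phase0_rad=0.5)
        spec, _ = simulate_spectrum(truth)
        out = phase_correct(spec, auto=True)
        assert abs(out.meta["phase0_applied"] - (-0.5)) < 0.02

    def test_real_only_spectrum_rejects_phase_request(self):
        s = Spectrum(np.linspace(-1, 1, 50), np.zeros(50))
        with pytest.raises(ValueError, match="imaginary"):
            phase_correct(s, phi0=0.3)


class TestAlignToPcr:
    def test_constructed_shift_recovered(self, full_noiseless):
        spec, _ = full_noiseless
        moved = Spectrum(spec.ppm + 0.30, spec.intensity)  # apex at -2.24
        out = align_to_pcr(moved)
        assert np.isclose(out.meta["ppm_shift_applied"], -0.30, atol=1e-3)
        assert np.isclose(out.meta["pcr_apex_found"], -2.24, atol=1e-3)

    def test_already_aligned_spectrum_unchanged(self, full_noiseless):
        spec, _ = full_noiseless
        out = align_to_pcr(spec)
        assert abs(out.meta["ppm_shift_applied"]) < 1e-4
        assert np.allclose(out.ppm, spec.ppm, atol=1e-4)

    def test_subgrid_offset_recovered_within_grid_spacing(self, full_noiseless):
        spec, _ = full_noiseless
        step = spec.ppm[1] - spec.ppm[0]
        moved = Spectrum(spec.ppm + 0.10, spec.intensity)
        out = align_to_pcr(moved)
        assert abs(out.meta["ppm_shift_applied"] + 0.10) < step

    def test_no_maximum_in_window_errors_with_window(self):
        x = np.linspace(-1, 1, 200)
        s = Spectrum(x, np.linspace(0, 1, 200))  # monotone ramp, no apex
        with pytest.raises(ValueError, match=r"\[-1.0, 1.0\]"):
            align_to_pcr(s, search_window=(-1.0, 1.0))


class TestBaselineCorrect:
    def test_zero_baseline_noiseless_estimate_small(self, full_noiseless):
        # the estimate can only approach zero down to the Lorentzian tail
        # floor (overlapping 1/x^2 tails are genuine signal everywhere)
        spec, _ = full_noiseless
        _, baseline = baseline_correct(spec)
        assert np.abs(baseline).max() < 0.01 * spec.intensity.max()

    def test_quadratic_drift_removed(self):
        truth = default_spectrum_truth(snr=20.0, seed=1)
        sd = truth.noise_sd
        truth = replace(truth, baseline_coeffs=(10 * sd, 0.0, 5 * sd / 30))
        spec, truth = simulate_spectrum(truth)
        corrected, _ = baseline_correct(spec)
        off = np.ones_like(spec.ppm, dtype=bool)
        for _n, c, _a, _w in truth.peaks:
            off &= np.abs(spec.ppm - c) > 1.0
        assert abs(np.median(corrected.intensity[off])) < 0.5 * sd

    def test_reapplication_changes_little(self):
        truth = default_spectrum_truth(snr=20.0, seed=2)
        sd = truth.noise_sd
        truth = replace(truth, baseline_coeffs=(5 * sd,))
        spec, truth = simulate_spectrum(truth)
        once, _ = baseline_correct(spec)
        twice, _ = baseline_correct(once)
        off = np.ones_like(spec.ppm, dtype=bool)
        for _n, c, _a, _w in truth.peaks:
            off &= np.abs(spec.ppm - c) > 1.0
        shift = np.median(twice.intensity[off]) - np.median(once.intensity[off])
        assert abs(shift) < 0.1 * sd

    def test_polynomial_fallback_removes_drift(self):
        truth = default_spectrum_truth(snr=np.inf)
        truth = replace(truth, baseline_coeffs=(1.0, 0.1, 0.05))
        spec, _ = simulate_spectrum(truth)
        corrected, baseline = baseline_correct(spec, method="poly")
        off = np.ones_like(spec.ppm, dtype=bool)
        for _n, c, _a, _w in truth.peaks:
            off &= np.abs(spec.ppm - c) > 1.0
        assert np.abs(corrected.intensity[off]).max() < 0.02 * spec.intensity.max()


class TestIntegration:
    def test_truncated_lorentzian_integral_analytic(self):
        # integral over +/-50 widths = (2/pi) atan(50) of the full pi*a*w
        a, w = 1.0, 0.1
        spec = lorentzian_spectrum(a=a, w=w, lo=-5.0, hi=5.0)
        area = integrate_window(spec, (-5.0, 5.0))
        expected = np.pi * a * w * (2 / np.pi) * np.arctan(50.0)
        assert np.isclose(area, expected, rtol=1e-4)

    def test_zero_spectrum_integrates_to_zero(self):
        s = Spectrum(np.linspace(-1, 1, 100), np.zeros(100))
        assert integrate_window(s, (-0.5, 0.5)) == 0.0

    def test_full_axis_matches_truth_area_within_1pct(self):
        truth = default_spectrum_truth(
            snr=np.inf, areas={k: 0.0 for k in
                ("gammaATP", "alphaATP", "NADplus", "NADH_cyt", "NADPplus",
                 "NADPH_cyt", "UDPglucose", "mitoNADPH")}
        )
        spec, truth = simulate_spectrum(truth)
        area = integrate_window(spec, (spec.ppm[0], spec.ppm[-1]))
        assert np.isclose(area, truth.areas["PCr"], rtol=0.01)

    def test_window_outside_axis_rejected(self):
        s = Spectrum(np.linspace(-1, 1, 100), np.zeros(100))
        with pytest.raises(ValueError, match="exceeds axis range"):
            integrate_window(s, (-2.0, 0.0))

    def test_empty_window_rejected(self):
        s = Spectrum(np.linspace(-1, 1, 100), np.zeros(100))
        with pytest.raises(ValueError, match="fewer than 2"):
            integrate_window(s, (0.0, 0.001))


class TestPcrAtpRatio:
    def test_equal_truth_areas_give_unit_ratio(self):
        truth = default_spectrum_truth(snr=np.inf, areas={"PCr": 1.0, "gammaATP": 1.0})
        spec, _ = simulate_spectrum(truth)
        assert np.isclose(pcr_atp_ratio(spec), 1.0, rtol=0.02)

    def test_degenerate_gamma_atp_rejected(self):
        # an empty spectrum has zero gamma-ATP area (with any peak present,
        # Lorentzian tails make every window integral slightly positive)
        truth = default_spectrum_truth(
            snr=np.inf, areas={k: 0.0 for k in
                ("PCr", "gammaATP", "alphaATP", "NADplus", "NADH_cyt",
                 "NADPplus", "NADPH_cyt", "UDPglucose", "mitoNADPH")}
        )
        spec, _ = simulate_spectrum(truth)
        with pytest.raises(ValueError, match="gamma-ATP"):
            pcr_atp_ratio(spec)
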