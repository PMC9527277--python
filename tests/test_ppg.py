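"""FIR vitals extraction: filters, peaks, rates, φ and SpO2 calibration."""

import numpy as np
import pytest
from scipy import signal as sps

from camvitals import ppg
from camvitals.ppg import (
    CARDIAC_BAND,
    RESPIRATORY_BAND,
    ChromoTimeSeries,
    FilterBand,
    FilteredSeries,
    SpO2Calibration,
    compute_phi,
    design_bandpass,
    detect_peaks,
    extract_ppg,
    fit_spo2_calibration,
    pulse_amplitudes,
    rate_from_peaks,
    spo2_from_phi,
)

FS = 15.0


def _gain(taps, f, fs=FS):
    w, h = sps.freqz(taps, worN=100_000, fs=fs)
    return np.abs(h)[np.argmin(np.abs(w - f))]


def _filtered(x, fs=FS, band=CARDIAC_BAND):
    x = np.asarray(x, dtype=float)
    return FilteredSeries(
        timestamps=np.arange(len(x)) / fs,
        values=x,
        valid=np.ones(len(x), dtype=bool),
        fs=fs,
        band=band,
    )


class TestDesignBandpass:
    @pytest.mark.parametrize(
        "band,n_taps", [(CARDIAC_BAND, 151), (RESPIRATORY_BAND, 2001)]
    )
    def test_band_contract(self, band, n_taps):
        taps = design_bandpass(band, FS, n_taps)
        assert _gain(taps, 0.0) < 1e-3  # DC blocked
        # passband within -3 dB at both nominal edges
        assert _gain(taps, band.low_hz) > 10 ** (-3 / 20)
        assert _gain(taps, band.high_hz) > 10 ** (-3 / 20)
        # stopband at half the low and 1.5x the high cut-off
        assert _gain(taps, 0.5 * band.low_hz) < 10 ** (-20 / 20)
        assert _gain(taps, 1.5 * band.high_hz) < 10 ** (-20 / 20)

    def test_cardiac_passes_1p2_hz(self):
        taps = design_bandpass(CARDIAC_BAND, FS, 151)
        assert 0.7 <= _gain(taps, 1.2) <= 1.1

    def test_respiratory_rejects_1p2_hz(self):
        taps = design_bandpass(RESPIRATORY_BAND, FS, 2001)
        assert _gain(taps, 1.2) < 0.1

    def test_infeasible_band_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            design_bandpass(FilterBand(0.75, 8.0), FS, 151)
        with pytest.raises(ValueError, match="odd"):
            design_bandpass(CARDIAC_BAND, FS, 150)

    def test_band_rate_correspondence(self):
        assert CARDIAC_BAND.rate_range_per_minute() == (45.0, 180.0)
        assert RESPIRATORY_BAND.rate_range_per_minute() == (3.0, 30.0)


def _series(chbo, chbr=None, fs=FS):
    chbo = np.asarray(chbo, dtype=float)
    chbr = chbo.copy() if chbr is None else np.asarray(chbr, dtype=float)
    t = np.arange(len(chbo)) / fs
    return ChromoTimeSeries(timestamps=t, chbo=chbo, chbr=chbr, fs=fs)


class TestExtractPpg:
    def test_pure_tone_passes_without_phase_lag(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        out = extract_ppg(_series(5.0 + x), CARDIAC_BAND, n_taps=151)
        y = out["chbt"]
        v = y.valid
        ref = 2 * x[v]  # chbt = chbo + chbr = 2x (the DC offset is removed)
        amp = np.ptp(y.values[v]) / np.ptp(ref)
        assert 0.9 < amp < 1.1
        lag = np.argmax(np.correlate(y.values[v], ref, "full")) - (v.sum() - 1)
        assert abs(lag) <= 1  # zero group delay after compensation

    def test_dc_only_input_filtered_to_zero(self):
        out = extract_ppg(_series(np.full(900, 3.7)), CARDIAC_BAND, n_taps=151)
        assert np.max(np.abs(out["chbt"].values)) < 1e-9

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(int(80 * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 1.2 * t)
        out = extract_ppg(_series(x), CARDIAC_BAND, n_taps=151)
        v = out["chbt"].valid
        spec = np.abs(np.fft.rfft(out["chbt"].values[v]))
        freqs = np.fft.rfftfreq(int(v.sum()), 1 / FS)
        a_low = spec[np.argmin(np.abs(freqs - 0.25))]
        a_pass = spec[np.argmin(np.abs(freqs - 1.2))]
        assert a_pass / max(a_low, 1e-12) > 10

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            extract_ppg(_series(np.zeros(100)), CARDIAC_BAND, n_taps=151)

    def test_causal_mode_matches_offline_in_steady_state(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        off = extract_ppg(_series(x), CARDIAC_BAND, n_taps=151, mode="offline")
        cau = extract_ppg(_series(x), CARDIAC_BAND, n_taps=151, mode="causal")
        mid = slice(400, 1200)
        assert np.corrcoef(off["chbt"].values[mid], cau["chbt"].values[mid])[0, 1] > 0.999


class TestDetectPeaks:
    def test_one_hz_sinusoid_peak_train(self):
        t = np.arange(int(30 * FS)) / FS
        peaks = detect_peaks(_filtered(np.sin(2 * np.pi * t)), min_separation_s=0.33)
        assert 29 <= len(peaks) <= 30
        np.testing.assert_allclose(np.diff(peaks), 1.0, atol=0.02)

    def test_all_zero_signal_gives_empty_list(self):
        peaks = detect_peaks(_filtered(np.zeros(300)), min_separation_s=0.33)
        assert len(peaks) == 0

    def test_beating_tones_respect_min_separation(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 1.05 * t)
        peaks = detect_peaks(_filtered(x), min_separation_s=60.0 / 180.0)
        assert np.all(np.diff(peaks) >= 60.0 / 180.0 - 1.0 / FS)


class TestRates:
    def test_exact_spacings(self):
        assert rate_from_peaks(np.arange(10.0)) == pytest.approx(60.0)
        assert rate_from_peaks(np.arange(0, 5, 0.5)) == pytest.approx(120.0)

    def test_fewer_than_two_peaks_flagged(self):
        assert np.isnan(rate_from_peaks(np.array([3.0]), window=(0, 10)))

    def test_noisy_72_bpm_recovery(self, rng):
        # 72 bpm tone with noise at 10 dB SNR through the cardiac band
        t = np.arange(int(60 * FS)) / FS
        clean = np.sin(2 * np.pi * 1.2 * t)
        noise = rng.normal(0, np.sqrt(0.5 / 10 ** (10 / 10)), len(t))
        out = extract_ppg(_series(clean + noise), CARDIAC_BAND, n_taps=151)
        peaks = detect_peaks(out["chbt"], min_separation_s=60.0 / 180.0)
        assert rate_from_peaks(peaks) == pytest.approx(72.0, abs=2.0)

    def test_scaling_invariance(self, rng):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 1.1 * t) + 0.1 * rng.normal(size=len(t))
        p1 = detect_peaks(_filtered(x), 0.4)
        p2 = detect_peaks(_filtered(137.0 * x), 0.4)
        np.testing.assert_array_equal(p1, p2)
        assert rate_from_peaks(p1) == rate_from_peaks(p2)


class TestPulseAmplitudes:
    def _peaks(self, x, fs=FS):
        return detect_peaks(_filtered(x, fs), min_separation_s=0.4)

    def test_proportional_channels(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        pa = pulse_amplitudes(_filtered(x), _filtered(2 * x), self._peaks(2 * x))
        np.testing.assert_allclose(pa["pa_hbr"], 2 * pa["pa_hbo"], rtol=1e-9)

    def test_sinusoid_amplitude_is_full_swing(self):
        t = np.arange(int(20 * FS)) / FS
        x = 0.7 * np.sin(2 * np.pi * 1.0 * t)
        pa = pulse_amplitudes(_filtered(x), _filtered(x), self._peaks(x))
        np.testing.assert_allclose(pa["pa_hbo"], 1.4, rtol=0.05)

    def test_zero_channel_gives_zero_amplitude(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        pa = pulse_amplitudes(_filtered(np.zeros_like(x)), _filtered(x), self._peaks(x))
        assert np.all(pa["pa_hbo"] == 0.0)

    def test_non_finite_beats_dropped_and_counted(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        bad = x.copy()
        bad[100:105] = np.nan
        pa = pulse_amplitudes(_filtered(bad), _filtered(x), self._peaks(x))
        assert pa.attrs["n_dropped"] > 0


class TestPhi:
    def test_equal_amplitudes(self):
        assert compute_phi([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_constant_ratio(self):
        assert compute_phi([2.0] * 5, [1.0] * 5) == 2.0

    def test_median_robust_to_outlier_beat(self):
        assert compute_phi([2.0, 4.0, 100.0], [1.0, 2.0, 1.0]) == 2.0

    def test_all_denominators_at_floor_flagged(self):
        assert np.isnan(compute_phi([1.0, 1.0], [0.0, 1e-15]))

    def test_scale_invariance_and_linearity(self, rng):
        pa_o = rng.uniform(1, 3, 20)
        pa_r = rng.uniform(1, 3, 20)
        base = compute_phi(pa_o, pa_r)
        assert compute_phi(5 * pa_o, 5 * pa_r) == pytest.approx(base)
        assert compute_phi(3 * pa_o, pa_r) == pytest.approx(3 * base)


class TestSpO2Calibration:
    A, B, C = -40.0, 0.8, 99.0

    def test_recovers_parameters_from_noisy_data(self, rng):
        phi = np.linspace(0.5, 4.0, 40)
        spo2 = self.A * np.exp(-phi / self.B) + self.C
        spo2 = spo2 + rng.normal(0, 0.005 * np.abs(spo2))  # 0.5 % noise
        cal = fit_spo2_calibration(phi, spo2)
        assert cal.a == pytest.approx(self.A, rel=0.10)
        assert cal.b == pytest.approx(self.B, rel=0.10)
        assert cal.c == pytest.approx(self.C, rel=0.10)

    def test_exact_data_interpolated(self):
        phi = np.linspace(0.5, 4.0, 20)
        spo2 = self.A * np.exp(-phi / self.B) + self.C
        cal = fit_spo2_calibration(phi, spo2)
        assert cal.residual_rms < 1e-8

    def test_curve_flat_above_phi_3(self):
        # steep below 2, nearly flat above 3
        from camvitals.synthetic import PhiCoupling

        cpl = PhiCoupling()
        phi = np.linspace(0.8, 4.5, 60)
        cal = fit_spo2_calibration(phi, cpl.spo2_from_phi(phi))
        slope_at_3 = -cal.a / cal.b * np.exp(-3.0 / cal.b)
        slope_at_1_5 = -cal.a / cal.b * np.exp(-1.5 / cal.b)
        assert abs(slope_at_3) < 1.0  # < 1 %-SpO2 per unit phi
        assert slope_at_1_5 > 5 * abs(slope_at_3)

    def test_narrow_phi_span_rejected(self):
        phi = np.linspace(2.0, 2.5, 10)
        with pytest.raises(ValueError, match="span"):
            fit_spo2_calibration(phi, self.A * np.exp(-phi / self.B) + self.C)

    def test_parameter_sign_constraints(self):
        with pytest.raises(ValueError):
            SpO2Calibration(a=5.0, b=1.0, c=99.0)
        with pytest.raises(ValueError):
            SpO2Calibration(a=-5.0, b=-1.0, c=99.0)
        with pytest.raises(ValueError):
            SpO2Calibration(a=-5.0, b=1.0, c=150.0)

    def test_json_round_trip(self, tmp_path):
        cal = SpO2Calibration(a=self.A, b=self.B, c=self.C)
        path = tmp_path / "cal.json"
        cal.to_json(path)
        back = SpO2Calibration.from_json(path)
        assert (back.a, back.b, back.c) == (self.A, self.B, self.C)


class TestSpO2FromPhi:
    CAL = SpO2Calibration(a=-40.0, b=0.8, c=99.0)

    def test_phi_zero_gives_a_plus_c(self):
        val, clamped = spo2_from_phi(0.0, self.CAL)
        assert val == pytest.approx(59.0)
        assert not clamped

    def test_large_phi_approaches_asymptote(self):
        val, _ = spo2_from_phi(50.0, self.CAL)
        assert val == pytest.approx(99.0, abs=1e-6)

    def test_monotone_increasing(self):
        phis = np.linspace(0, 5, 50)
        vals = [spo2_from_phi(p, self.CAL)[0] for p in phis]
        assert np.all(np.diff(vals) >= 0)

    def test_clamping_flagged(self):
        cal = SpO2Calibration(a=-200.0, b=0.8, c=99.0)
        val, clamped = spo2_from_phi(0.0, cal)
        assert val == 0.0 and clamped

    def test_nan_phi_flagged_missing(self):
        val, clamped = spo2_from_phi(float("nan"), self.CAL)
        assert np.isnan(val) and not clamped


class TestBandOverlap:
    def test_overlapping_bands_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            ppg.check_band_overlap(FilterBand(0.4, 3.0), RESPIRATORY_BAND)

    def test_default_bands_do_not_warn(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert not ppg.check_band_overlap(CARDIAC_BAND, RESPIRATORY_BAND)
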