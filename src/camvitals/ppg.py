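"""PPG signal extraction and vital-sign computation.

Two linear-phase FIR bandpass filters isolate the cardiac (0.75–3 Hz) and
respiratory (0.05–0.5 Hz) components of the hemoglobin time series; those
bands correspond to pulse rates of 45–180 bpm and respiratory rates of
3–30 rpm.  Rates come from median inter-peak intervals, the per-beat
pulse-amplitude ratio φ = PA_HbO/PA_HbR feeds an exponential SpO2
calibration SpO2(φ) = A·exp(−φ/B) + C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d
from scipy.optimize import least_squares

__all__ = [
    "FilterBand",
    "CARDIAC_BAND",
    "RESPIRATORY_BAND",
    "ChromoTimeSeries",
    "SpO2Calibration",
    "design_bandpass",
    "extract_ppg",
    "detect_peaks",
    "rate_from_peaks",
    "pulse_amplitudes",
    "compute_phi",
    "fit_spo2_calibration",
    "spo2_from_phi",
]


@dataclass(frozen=True)
class FilterBand:
    low_hz: float
    high_hz: float
    role: str = "cardiac"  # or "respiratory"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low < high")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cut-off {self.high_hz} Hz infeasible at fs={fs} Hz"
            )

    def rate_range_per_minute(self) -> tuple[float, float]:
        """The band expressed as events per minute (bpm or rpm)."""
        return 60.0 * self.low_hz, 60.0 * self.high_hz


CARDIAC_BAND = FilterBand(0.75, 3.0, "cardiac")
RESPIRATORY_BAND = FilterBand(0.05, 0.5, "respiratory")

#: default tap counts per role at fs = 15 Hz; the respiratory band needs a
#: much longer filter to hold its stopband at half the 0.05 Hz cut-off
DEFAULT_TAPS = {"cardiac": 151, "respiratory": 2001}


@dataclass
class ChromoTimeSeries:
    """Uniformly sampled ROI-mean chromophore time series."""

    timestamps: np.ndarray  # s
    chbo: np.ndarray
    chbr: np.ndarray
    chbt: np.ndarray | None = None
    sto2: np.ndarray | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.chbo = np.asarray(self.chbo, dtype=float)
        self.chbr = np.asarray(self.chbr, dtype=float)
        if self.chbt is None:
            self.chbt = self.chbo + self.chbr
        else:
            self.chbt = np.asarray(self.chbt, dtype=float)
        dt = np.diff(self.timestamps)
        if len(dt):
            fs = 1.0 / np.median(dt)
            if self.fs is None:
                self.fs = float(fs)
            if np.any(np.abs(dt - 1.0 / self.fs) > 0.5 / self.fs):
                raise ValueError("sampling jitter exceeds half a sample interval")
        for arr in (self.chbo, self.chbr, self.chbt):
            if not np.all(np.isfinite(arr)):
                raise ValueError("chromophore series must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)


def design_bandpass(
    band: FilterBand, fs: float, n_taps: int | None = None
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR bandpass.

    Design cut-offs are widened by half the transition width so the nominal
    band edges sit near unity gain rather than at the −6 dB points.
    """
    if n_taps is None:
        n_taps = DEFAULT_TAPS.get(band.role, 151)
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd (type-I linear phase)")
    band.validate(fs)
    transition = 3.3 * fs / n_taps  # Hamming main-lobe width, Hz
    lo = max(band.low_hz - transition / 2.0, transition / 20.0)
    hi = min(band.high_hz + transition / 2.0, fs / 2.0 * 0.999)
    if lo >= hi:
        raise ValueError("band infeasible: widened edges collapse")
    taps = sps.firwin(n_taps, [lo, hi], pass_zero=False, window="hamming", fs=fs)
    taps = taps - taps.mean()  # exact DC null; passband change is O(1/n_taps)
    return taps


@dataclass
class FilteredSeries:
    timestamps: np.ndarray
    values: np.ndarray
    valid: np.ndarray  # bool mask; False inside the filter edge regions
    fs: float
    band: FilterBand


def _filter_channel(x, taps, fs, mode):
    x = np.asarray(x, dtype=float)
    x = x - x.mean()  # the bandpass removes DC anyway; improves edge behavior
    if mode == "offline":
        return sps.filtfilt(taps, [1.0], x)
    # causal filtering with group-delay compensation: a linear-phase FIR
    # delays by (n_taps-1)/2 samples, so shift the output back
    y = sps.lfilter(taps, [1.0], x)
    delay = (len(taps) - 1) // 2
    out = np.empty_like(y)
    out[:-delay] = y[delay:]
    out[-delay:] = 0.0
    return out


def extract_ppg(
    series: ChromoTimeSeries,
    band: FilterBand,
    n_taps: int | None = None,
    mode: str = "offline",
) -> dict[str, FilteredSeries]:
    """Bandpass-filter CHbO, CHbR and CHbT.

    Offline mode applies the FIR forward-backward (zero phase); streaming
    ("causal") mode applies it causally and shifts timestamps by the group
    delay.  Samples within half the filter length of either end are flagged
    invalid.
    """
    if mode not in ("offline", "causal"):
        raise ValueError("mode must be 'offline' or 'causal'")
    if n_taps is None:
        n_taps = DEFAULT_TAPS.get(band.role, 151)
    if len(series) < 3 * n_taps:
        raise ValueError(
            f"series of {len(series)} samples is too short for a "
            f"{n_taps}-tap filter (need >= {3 * n_taps})"
        )
    fs = series.fs
    taps = design_bandpass(band, fs, n_taps)
    edge = n_taps // 2
    valid = np.ones(len(series), dtype=bool)
    valid[:edge] = False
    valid[len(series) - edge :] = False
    out = {}
    for name, x in (("chbo", series.chbo), ("chbr", series.chbr), ("chbt", series.chbt)):
        y = _filter_channel(x, taps, fs, mode)
        out[name] = FilteredSeries(
            timestamps=series.timestamps, values=y, valid=valid.copy(), fs=fs, band=band
        )
    return out


def check_band_overlap(cardiac: FilterBand, respiratory: FilterBand) -> bool:
    """Warn (never raise) if the two bands overlap."""
    overlap = cardiac.low_hz < respiratory.high_hz and respiratory.low_hz < cardiac.high_hz
    if overlap:
        warnings.warn(
            "cardiac and respiratory filter bands overlap; pulse and "
            "respiratory signals may be indistinguishable",
            stacklevel=2,
        )
    return overlap


def detect_peaks(
    filtered: FilteredSeries, min_separation_s: float
) -> np.ndarray:
    """Peak times of a filtered series.

    Local maxima separated by at least ``min_separation_s`` and exceeding
    0.3× a rolling amplitude envelope (a moving maximum of |x| spanning two
    minimum separations).  Returns strictly increasing times; may be empty.
    """
    x = np.where(filtered.valid, filtered.values, 0.0)
    n_sep = max(1, int(round(min_separation_s * filtered.fs)))
    envelope = maximum_filter1d(np.abs(x), size=4 * n_sep + 1, mode="nearest")
    idx, _ = sps.find_peaks(x, distance=n_sep)
    if len(idx):
        keep = x[idx] > 0.3 * envelope[idx]
        keep &= filtered.valid[idx]
        idx = idx[keep]
    if len(idx) == 0:
        return filtered.timestamps[:0]
    # sub-sample refinement: parabola through the three samples around each
    # peak, so inter-peak intervals are not quantized to the frame grid
    times = filtered.timestamps[idx].astype(float).copy()
    dt = 1.0 / filtered.fs
    inner = (idx > 0) & (idx < len(x) - 1)
    ii = idx[inner]
    denom = x[ii - 1] - 2.0 * x[ii] + x[ii + 1]
    ok = np.abs(denom) > 0
    delta = np.zeros(len(ii))
    delta[ok] = 0.5 * (x[ii - 1] - x[ii + 1])[ok] / denom[ok]
    times[inner] += np.clip(delta, -0.5, 0.5) * dt
    return times


def rate_from_peaks(
    peak_times: np.ndarray, window: tuple[float, float] | None = None
) -> float:
    """Rate per minute from the median inter-peak interval in a window.

    Returns NaN when fewer than two peaks fall inside the window.
    """
    t = np.asarray(peak_times, dtype=float)
    if window is not None:
        t = t[(t >= window[0]) & (t < window[1])]
    if len(t) < 2:
        return float("nan")
    return 60.0 / float(np.median(np.diff(t)))


def pulse_amplitudes(
    filtered_chbo: FilteredSeries,
    filtered_chbr: FilteredSeries,
    peak_times: np.ndarray,
) -> pd.DataFrame:
    """Per-beat pulse-wave amplitudes PA_HbO and PA_HbR.

    For each cardiac peak (after the first), the amplitude on each channel
    is the channel value at the peak minus its minimum over the preceding
    half inter-beat interval, evaluated at the same beat boundaries.
    Beats containing non-finite samples are dropped and counted in
    ``attrs['n_dropped']``.
    """
    t = filtered_chbo.timestamps
    fs = filtered_chbo.fs
    peaks = np.asarray(peak_times, dtype=float)
    rows = []
    n_dropped = 0
    for k in range(1, len(peaks)):
        ibi = peaks[k] - peaks[k - 1]
        i_pk = int(round((peaks[k] - t[0]) * fs))
        i_lo = int(round((peaks[k] - 0.5 * ibi - t[0]) * fs))
        i_pk = min(max(i_pk, 0), len(t) - 1)
        i_lo = min(max(i_lo, 0), i_pk)
        seg_o = filtered_chbo.values[i_lo : i_pk + 1]
        seg_r = filtered_chbr.values[i_lo : i_pk + 1]
        if len(seg_o) == 0 or not (
            np.all(np.isfinite(seg_o)) and np.all(np.isfinite(seg_r))
        ):
            n_dropped += 1
            continue
        rows.append(
            {
                "peak_time": peaks[k],
                "pa_hbo": filtered_chbo.values[i_pk] - seg_o.min(),
                "pa_hbr": filtered_chbr.values[i_pk] - seg_r.min(),
            }
        )
    df = pd.DataFrame(rows, columns=["peak_time", "pa_hbo", "pa_hbr"])
    df.attrs["n_dropped"] = n_dropped
    return df


def compute_phi(pa_hbo, pa_hbr, floor: float = 1e-12) -> float:
    """Window-level φ: the median over beats of PA_HbO/PA_HbR.

    Returns NaN when no valid beats remain (all PA_HbR at the numeric
    floor).
    """
    pa_hbo = np.asarray(pa_hbo, dtype=float)
    pa_hbr = np.asarray(pa_hbr, dtype=float)
    if pa_hbo.shape != pa_hbr.shape:
        raise ValueError("amplitude lists must align beat-by-beat")
    ok = np.isfinite(pa_hbo) & np.isfinite(pa_hbr) & (np.abs(pa_hbr) > floor)
    if not np.any(ok):
        return float("nan")
    return float(np.median(pa_hbo[ok] / pa_hbr[ok]))


@dataclass
class SpO2Calibration:
    """Exponential SpO2(φ) = A·exp(−φ/B) + C with A < 0, B > 0."""

    a: float
    b: float
    c: float
    residual_rms: float = float("nan")
    phi_range: tuple[float, float] = (float("nan"), float("nan"))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.a < 0:
            raise ValueError("A must be negative (SpO2 rises toward its asymptote)")
        if not self.b > 0:
            raise ValueError("B must be positive")
        if not 0 < self.c <= 110:
            raise ValueError("asymptote C must lie in (0, 110]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "A": self.a,
                    "B": self.b,
                    "C": self.c,
                    "residual_rms": self.residual_rms,
                    "phi_range": list(self.phi_range),
                    "metadata": self.metadata,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SpO2Calibration":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            a=p["A"],
            b=p["B"],
            c=p["C"],
            residual_rms=p.get("residual_rms", float("nan")),
            phi_range=tuple(p.get("phi_range", (float("nan"), float("nan")))),
            metadata=p.get("metadata", {}),
        )


def fit_spo2_calibration(phi_values, spo2_values) -> SpO2Calibration:
    """Bounded nonlinear least squares for (A, B, C)."""
    phi = np.asarray(phi_values, dtype=float)
    ref = np.asarray(spo2_values, dtype=float)
    ok = np.isfinite(phi) & np.isfinite(ref)
    phi, ref = phi[ok], ref[ok]
    if len(phi) < 5:
        raise ValueError("need at least 5 (phi, SpO2) pairs")
    span = phi.max() - phi.min()
    if span < 1.0:
        raise ValueError(
            f"phi span {span:.2f} too narrow to constrain the exponential "
            "(need >= 1.0)"
        )

    def residual(p):
        a, b, c = p
        return a * np.exp(-phi / b) + c - ref

    c0 = min(float(ref.max()) + 0.5, 110.0)
    a0 = min(float(ref.min()) - c0, -1.0)
    res = least_squares(
        residual,
        x0=[a0, 1.0, c0],
        bounds=([-1e6, 1e-3, 1e-3], [-1e-9, 1e3, 110.0]),
        method="trf",
    )
    if not res.success:
        raise RuntimeError(f"SpO2 calibration fit failed: {res.message}")
    a, b, c = res.x
    return SpO2Calibration(
        a=float(a),
        b=float(b),
        c=float(c),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        phi_range=(float(phi.min()), float(phi.max())),
        metadata={"n_pairs": int(len(phi))},
    )


def spo2_from_phi(phi: float, calibration: SpO2Calibration) -> tuple[float, bool]:
    """Evaluate the calibration; returns (SpO2 %, clamped_flag).

    NaN φ propagates to a flagged missing value.
    """
    if not np.isfinite(phi):
        return float("nan"), False
    raw = calibration.a * np.exp(-phi / calibration.b) + calibration.c
    clamped = raw < 0.0 or raw > 100.0
    return float(np.clip(raw, 0.0, 100.0)), bool(clamped)
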