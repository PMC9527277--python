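"""End-to-end orchestration: video → XYZ → chromophore maps → vitals.

Frames are flat-field corrected with a white-diffuser reference, mapped to
XYZ with M1 and to chromophore concentrations with M2; ROI statistics form
the hemoglobin time series from which windowed PR, RR, SpO2 and StO2
estimates are computed.

Coordinate convention: 0-based (row, col) with half-open extents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from . import colorimetry, inverse_mapping, ppg

__all__ = [
    "VideoSource",
    "RoiSpec",
    "PipelineConfig",
    "flat_field_correct",
    "roi_series",
    "subregion_variability",
    "run_pipeline",
]

#: reflectance of the white reference diffuser
DIFFUSER_REFLECTANCE = 0.99


@dataclass
class VideoSource:
    """A frame stream with constant shape and known frame rate."""

    frames: Iterable[np.ndarray]  # each (H, W, 3)
    fs: float  # Hz
    bit_depth: int = 8

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @classmethod
    def from_array(cls, array: np.ndarray, fs: float, bit_depth: int = 8) -> "VideoSource":
        if array.ndim != 4 or array.shape[-1] != 3:
            raise ValueError("expected (T, H, W, 3) array")
        return cls(frames=array, fs=fs, bit_depth=bit_depth)

    @classmethod
    def from_directory(cls, path, fs: float, pattern: str = "*.png") -> "VideoSource":
        import imageio.v3 as iio
        from pathlib import Path

        files = sorted(Path(path).glob(pattern))
        if not files:
            raise FileNotFoundError(f"no frames matching {pattern} under {path}")

        def gen():
            for f in files:
                yield iio.imread(f)

        return cls(frames=gen(), fs=fs)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI: top-left (row, col), height, width in pixels."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("ROI must be at least 2x2 so quadrants are non-empty")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, frame_shape) -> None:
        h, w = frame_shape[:2]
        if self.row + self.height > h or self.col + self.width > w:
            raise ValueError(
                f"ROI {self} does not fit inside frame of shape {frame_shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.height),
            slice(self.col, self.col + self.width),
        )

    def quadrants(self) -> list["RoiSpec"]:
        """Four near-equal (±1 px) sub-regions."""
        h2, w2 = self.height // 2, self.width // 2
        return [
            RoiSpec(self.row, self.col, h2, w2),
            RoiSpec(self.row, self.col + w2, h2, self.width - w2),
            RoiSpec(self.row + h2, self.col, self.height - h2, w2),
            RoiSpec(self.row + h2, self.col + w2, self.height - h2, self.width - w2),
        ]

    @classmethod
    def centered(cls, frame_shape, size: int = 300) -> "RoiSpec":
        h, w = frame_shape[:2]
        size = min(size, h, w)
        return cls((h - size) // 2, (w - size) // 2, size, size)


@dataclass
class PipelineConfig:
    cardiac_band: ppg.FilterBand = ppg.CARDIAC_BAND
    respiratory_band: ppg.FilterBand = ppg.RESPIRATORY_BAND
    cardiac_taps: int = 151
    respiratory_taps: int = 2001
    pr_window_s: float = 20.0
    pr_step_s: float = 1.0
    rr_window_s: float = 60.0
    rr_step_s: float = 5.0
    roi: RoiSpec | None = None  # None -> centered 300x300 (clipped to frame)
    mode: str = "offline"  # or "streaming"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cardiac_band" in raw:
            lo, hi = raw["cardiac_band"]
            kwargs["cardiac_band"] = ppg.FilterBand(lo, hi, "cardiac")
        if "respiratory_band" in raw:
            lo, hi = raw["respiratory_band"]
            kwargs["respiratory_band"] = ppg.FilterBand(lo, hi, "respiratory")
        for key in (
            "cardiac_taps",
            "respiratory_taps",
            "pr_window_s",
            "pr_step_s",
            "rr_window_s",
            "rr_step_s",
            "mode",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "roi" in raw:
            kwargs["roi"] = RoiSpec(**raw["roi"])
        return cls(**kwargs)


def flat_field_correct(
    frame: np.ndarray,
    diffuser_frame: np.ndarray,
    mode: str = "reflectance",
    eps_fraction: float = 1e-3,
) -> np.ndarray:
    """Correct illumination nonuniformity with a white-diffuser reference.

    ``reflectance`` mode (default) divides each pixel/channel by the
    illumination estimate diffuser/0.99, yielding frames in units of scene
    reflectance relative to a perfect white; this removes the vignette and
    the illuminant color in one step (the diffuser serves both flat-field
    and white-balance duty), making downstream results invariant to global
    illumination scaling.  ``mean`` mode preserves the original intensity
    scale and removes only the spatial pattern.

    Near-zero diffuser pixels are masked to NaN in the output.
    """
    frame = np.asarray(frame, dtype=float)
    diff = np.asarray(diffuser_frame, dtype=float)
    if frame.shape != diff.shape:
        raise ValueError("frame and diffuser frame shapes must match")
    thresh = eps_fraction * np.nanmax(diff)
    bad = diff <= thresh
    safe = np.where(bad, 1.0, diff)
    if mode == "reflectance":
        out = frame * DIFFUSER_REFLECTANCE / safe
    elif mode == "mean":
        masked = np.where(bad, np.nan, diff)
        channel_mean = np.nanmean(masked.reshape(-1, diff.shape[-1]), axis=0)
        out = frame * channel_mean / safe
    else:
        raise ValueError("mode must be 'reflectance' or 'mean'")
    out[bad] = np.nan
    return out


def _map_arrays(maps: inverse_mapping.ChromophoreMaps) -> dict[str, np.ndarray]:
    return {
        "chbo": maps.chbo,
        "chbr": maps.chbr,
        "chbt": maps.chbt,
        "sto2": maps.sto2,
    }


def roi_series(
    map_stream: Iterable[inverse_mapping.ChromophoreMaps],
    roi: RoiSpec,
    fs: float,
) -> pd.DataFrame:
    """Per-frame spatial mean and SD over the ROI for each chromophore.

    Frames where more than half the ROI pixels are flagged (NaN) are marked
    ``low_quality``.
    """
    rows = []
    sl = roi.slices()
    for t_idx, maps in enumerate(map_stream):
        row = {"time_s": t_idx / fs}
        n_bad_max = 0
        for name, arr in _map_arrays(maps).items():
            patch = arr[sl]
            n_bad = int(np.sum(~np.isfinite(patch)))
            n_bad_max = max(n_bad_max, n_bad)
            row[f"{name}_mean"] = (
                float(np.nanmean(patch)) if n_bad < patch.size else np.nan
            )
            row[f"{name}_sd"] = (
                float(np.nanstd(patch)) if n_bad < patch.size else np.nan
            )
        row["low_quality"] = n_bad_max > 0.5 * roi.height * roi.width
        rows.append(row)
    return pd.DataFrame(rows)


def subregion_variability(
    map_stream: Iterable[inverse_mapping.ChromophoreMaps],
    roi: RoiSpec,
    fs: float,
) -> pd.DataFrame:
    """Across-quadrant SD (sample SD, n−1) per frame and quantity."""
    quads = [q.slices() for q in roi.quadrants()]
    rows = []
    for t_idx, maps in enumerate(map_stream):
        row = {"time_s": t_idx / fs}
        for name, arr in _map_arrays(maps).items():
            means = [np.nanmean(arr[sl]) for sl in quads]
            row[f"{name}_quadrant_sd"] = float(np.std(means, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def frames_to_series(
    video: VideoSource,
    m1: colorimetry.M1Transform,
    m2: inverse_mapping.M2Transform,
    diffuser_frame: np.ndarray | None,
    roi: RoiSpec | None,
    flat_field_mode: str = "reflectance",
) -> tuple[ppg.ChromoTimeSeries, pd.DataFrame]:
    """Reduce a video to the ROI-mean chromophore time series."""
    rows = []
    roi_actual = roi
    for idx, frame in enumerate(video):
        if roi_actual is None:
            roi_actual = RoiSpec.centered(frame.shape)
            roi_actual.validate(frame.shape)
        if diffuser_frame is not None:
            frame = flat_field_correct(frame, diffuser_frame, mode=flat_field_mode)
        sl = roi_actual.slices()
        patch = np.asarray(frame, dtype=float)[sl]
        xyz = colorimetry.rgb_to_xyz(patch, m1)
        maps = inverse_mapping.estimate_concentrations(
            np.nan_to_num(xyz, nan=0.0), m2
        )
        row = {"time_s": idx / video.fs}
        for name, arr in _map_arrays(maps).items():
            row[f"{name}_mean"] = float(np.nanmean(arr))
            row[f"{name}_sd"] = float(np.nanstd(arr))
        row["n_negative"] = maps.n_negative
        rows.append(row)
    df = pd.DataFrame(rows)
    series = ppg.ChromoTimeSeries(
        timestamps=df["time_s"].to_numpy(),
        chbo=df["chbo_mean"].to_numpy(),
        chbr=df["chbr_mean"].to_numpy(),
        fs=video.fs,
    )
    return series, df


def _windows(t0: float, t1: float, width: float, step: float):
    start = t0
    while start + width <= t1 + 1e-9:
        yield (start, start + width)
        start += step


def vitals_from_series(
    series: ppg.ChromoTimeSeries,
    frame_stats: pd.DataFrame,
    calibration: ppg.SpO2Calibration | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Windowed PR/RR/SpO2/StO2 estimates from a chromophore time series.

    PR, φ and SpO2 use a sliding cardiac window (default 20 s / 1 s step);
    RR uses a longer respiratory window (default 60 s / 5 s step) and each
    cardiac window reports the RR of the nearest respiratory window.  StO2
    is the raw (unfiltered) ROI-mean over the window.
    """
    ppg.check_band_overlap(config.cardiac_band, config.respiratory_band)
    mode = "offline" if config.mode == "offline" else "causal"
    cardiac = ppg.extract_ppg(
        series, config.cardiac_band, n_taps=config.cardiac_taps, mode=mode
    )
    resp = ppg.extract_ppg(
        series, config.respiratory_band, n_taps=config.respiratory_taps, mode=mode
    )
    cardiac_peaks = ppg.detect_peaks(cardiac["chbt"], min_separation_s=60.0 / 180.0)
    resp_peaks = ppg.detect_peaks(resp["chbt"], min_separation_s=60.0 / 30.0)
    amplitudes = ppg.pulse_amplitudes(cardiac["chbo"], cardiac["chbr"], cardiac_peaks)

    t0, t1 = series.timestamps[0], series.timestamps[-1]

    rr_rows = []
    for lo, hi in _windows(t0, t1, config.rr_window_s, config.rr_step_s):
        rr_rows.append(
            {"center": 0.5 * (lo + hi), "rr": ppg.rate_from_peaks(resp_peaks, (lo, hi))}
        )
    rr_df = pd.DataFrame(rr_rows)

    sto2_mean = frame_stats["sto2_mean"].to_numpy()
    times = series.timestamps
    records = []
    for lo, hi in _windows(t0, t1, config.pr_window_s, config.pr_step_s):
        pr = ppg.rate_from_peaks(cardiac_peaks, (lo, hi))
        in_win = amplitudes[
            (amplitudes["peak_time"] >= lo) & (amplitudes["peak_time"] < hi)
        ]
        phi = (
            ppg.compute_phi(in_win["pa_hbo"], in_win["pa_hbr"])
            if len(in_win)
            else float("nan")
        )
        if calibration is not None and np.isfinite(phi):
            spo2, clamped = ppg.spo2_from_phi(phi, calibration)
        else:
            spo2, clamped = float("nan"), False
        sel = (times >= lo) & (times < hi)
        sto2 = float(np.nanmean(sto2_mean[sel])) if np.any(sel) else float("nan")
        if len(rr_df):
            k = int(np.argmin(np.abs(rr_df["center"].to_numpy() - 0.5 * (lo + hi))))
            rr = float(rr_df["rr"].iloc[k])
            rr_matched = (
                abs(rr_df["center"].iloc[k] - 0.5 * (lo + hi)) <= config.rr_window_s
            )
        else:
            rr, rr_matched = float("nan"), False
        flags = []
        if not np.isfinite(pr):
            flags.append("pr_missing")
        elif not 45.0 <= pr <= 180.0:
            flags.append("pr_out_of_range")
        if not (np.isfinite(rr) and rr_matched):
            flags.append("rr_missing")
            rr = float("nan")
        elif not 3.0 <= rr <= 30.0:
            flags.append("rr_out_of_range")
        if not np.isfinite(spo2):
            flags.append("spo2_missing")
        if clamped:
            flags.append("spo2_clamped")
        records.append(
            {
                "window_start": lo,
                "window_end": hi,
                "PR": pr,
                "RR": rr,
                "SpO2": spo2,
                "StO2": sto2,
                "phi": phi,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(records)


def run_pipeline(
    video: VideoSource,
    m1: colorimetry.M1Transform,
    m2: inverse_mapping.M2Transform,
    calibration: ppg.SpO2Calibration | None = None,
    config: PipelineConfig | None = None,
    diffuser_frame: np.ndarray | None = None,
) -> dict:
    """Full video → vitals chain.

    Returns a dict with the per-window ``vitals`` DataFrame, the per-frame
    ``frame_stats`` and the ROI chromophore ``series``.  Band/frame-rate
    compatibility is checked up front so incompatible configs fail at
    startup rather than mid-run.
    """
    config = config or PipelineConfig()
    config.cardiac_band.validate(video.fs)
    config.respiratory_band.validate(video.fs)
    series, frame_stats = frames_to_series(video, m1, m2, diffuser_frame, config.roi)
    vitals = vitals_from_series(series, frame_stats, calibration, config)
    return {"vitals": vitals, "frame_stats": frame_stats, "series": series}
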