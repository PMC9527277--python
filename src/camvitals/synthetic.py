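"""Ground-truthed synthetic data: scenarios, rendered video, reference traces.

The generator emulates a forehead ROI whose reflectance is driven by
time-varying hemoglobin concentrations: a cardiac oscillation at the
instantaneous pulse rate (an asymmetric systolic waveform, so peak
detection is exercised realistically), a slower respiratory modulation of
total hemoglobin, and an optional hypoxia episode during which SpO2/StO2
fall and recover.  The default scenario mirrors a 9-minute protocol with a
4-minute desaturation episode dipping to about 87 % SpO2 and 77 % StO2.

The arterial pulse is split between the HbO and HbR channels so that the
pulse-amplitude ratio φ = PA_HbO/PA_HbR falls as SpO2 falls, following an
exponential φ↔SpO2 coupling spanning roughly φ ∈ [1, 4] over
SpO2 ∈ [86, 100] % (steep below φ = 2, nearly flat above 3).

Rendering closes the loop: chromophores → Monte-Carlo skin reflectance →
XYZ → synthetic linear camera RGB with vignetting, sensor noise and 8-bit
quantization, plus a matching white-diffuser frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colorimetry, spectra
from .forward_model import ChromophoreState, SkinModel, white_path_survey
from .ppg import ChromoTimeSeries

__all__ = [
    "PhiCoupling",
    "Scenario",
    "ScenarioSeries",
    "generate_scenario_series",
    "ReflectanceEmulator",
    "SyntheticCamera",
    "make_color_checker",
    "render_video",
    "generate_reference_traces",
]


@dataclass(frozen=True)
class PhiCoupling:
    """Exponential SpO2(φ) = A·exp(−φ/B) + C used to couple pulse
    amplitudes to arterial saturation.  ``fixed_phi`` overrides the curve
    with a constant ratio (useful for symmetric test scenarios)."""

    a: float = -65.0
    b: float = 0.65
    c: float = 100.0
    fixed_phi: float | None = None

    def phi_from_spo2(self, spo2):
        if self.fixed_phi is not None:
            return np.full_like(np.asarray(spo2, dtype=float), self.fixed_phi)
        s = np.asarray(spo2, dtype=float)
        if np.any(s >= self.c):
            raise ValueError(
                f"SpO2 must stay below the calibration asymptote C={self.c}"
            )
        return -self.b * np.log((s - self.c) / self.a)

    def spo2_from_phi(self, phi):
        return self.a * np.exp(-np.asarray(phi, dtype=float) / self.b) + self.c


@dataclass(frozen=True)
class Scenario:
    """Physiologic ground-truth specification for one synthetic recording."""

    duration_s: float = 540.0
    fs: float = 15.0
    baseline: ChromophoreState = field(
        default_factory=lambda: ChromophoreState(cm=0.04, chbo=0.0088, chbr=0.0012)
    )
    pr_bpm: float = 72.0
    pr_hypoxia_rise_bpm: float = 8.0
    rr_rpm: float = 15.0
    rr_hypoxia_drop_rpm: float = 1.5
    spo2_normal: float = 99.0
    spo2_hypoxia: float = 87.0
    sto2_normal: float = 88.0  # tissue pool mixes venous blood; ~85-90 % is realistic
    sto2_hypoxia: float = 77.0
    hypoxia_onset_s: float | None = 150.0  # None disables the episode
    hypoxia_duration_s: float = 240.0
    ramp_s: float = 60.0
    cardiac_depth: float = 0.05  # pulse amplitude as a fraction of CHbT
    respiratory_depth: float = 0.025
    coupling: PhiCoupling = field(default_factory=PhiCoupling)
    series_noise_sd: float = 0.0  # additive noise on CHbO/CHbR, model units

    def __post_init__(self) -> None:
        for depth in (self.cardiac_depth, self.respiratory_depth):
            if not 0.0 <= depth < 0.5:
                raise ValueError("modulation depths must lie in [0, 0.5)")
        for v in (
            self.spo2_normal,
            self.spo2_hypoxia,
            self.sto2_normal,
            self.sto2_hypoxia,
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError("saturation trajectories must stay in [0, 100] %")

    # --- trajectories -----------------------------------------------------
    def episode_envelope(self, t):
        """0 → 1 → 0 envelope of the hypoxia episode with cosine ramps."""
        t = np.asarray(t, dtype=float)
        if self.hypoxia_onset_s is None:
            return np.zeros_like(t)
        on = self.hypoxia_onset_s
        off = on + self.hypoxia_duration_s
        r = self.ramp_s
        env = np.zeros_like(t)
        rising = (t >= on) & (t < on + r)
        env[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - on) / r))
        env[(t >= on + r) & (t < off)] = 1.0
        falling = (t >= off) & (t < off + r)
        env[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - off) / r))
        return env

    def pr_at(self, t):
        return self.pr_bpm + self.pr_hypoxia_rise_bpm * self.episode_envelope(t)

    def rr_at(self, t):
        return self.rr_rpm - self.rr_hypoxia_drop_rpm * self.episode_envelope(t)

    def spo2_at(self, t):
        return self.spo2_normal - (self.spo2_normal - self.spo2_hypoxia) * (
            self.episode_envelope(t)
        )

    def sto2_at(self, t):
        return self.sto2_normal - (self.sto2_normal - self.sto2_hypoxia) * (
            self.episode_envelope(t)
        )


@dataclass
class ScenarioSeries:
    """Generated chromophore series plus instantaneous ground truth."""

    scenario: Scenario
    series: ChromoTimeSeries
    truth: pd.DataFrame  # per-sample pr, rr, spo2, sto2, phi
    seed: int

    def truth_windows(self, width_s: float, step_s: float) -> pd.DataFrame:
        """Window means of the ground-truth trajectories."""
        t = self.truth["time_s"].to_numpy()
        rows = []
        start = t[0]
        while start + width_s <= t[-1] + 1e-9:
            sel = (t >= start) & (t < start + width_s)
            win = self.truth[sel]
            rows.append(
                {
                    "window_start": start,
                    "window_end": start + width_s,
                    "pr": win["pr"].mean(),
                    "rr": win["rr"].mean(),
                    "spo2": win["spo2"].mean(),
                    "sto2": win["sto2"].mean(),
                    "phi": win["phi"].mean(),
                }
            )
            start += step_s
        return pd.DataFrame(rows)


def _pulse_waveform(phase):
    """Asymmetric cardiac waveform on phase ∈ [0, 1): a narrow systolic
    upstroke with a smaller dicrotic bump."""
    u = np.mod(phase, 1.0)
    return np.exp(-0.5 * ((u - 0.25) / 0.07) ** 2) + 0.35 * np.exp(
        -0.5 * ((u - 0.55) / 0.12) ** 2
    )


def generate_scenario_series(scenario: Scenario, seed: int = 0) -> ScenarioSeries:
    """Synthesize CHbO(t)/CHbR(t) with known PR, RR, SpO2, StO2 and φ.

    The baseline (venous + capillary) hemoglobin pool follows the StO2
    trajectory; the zero-mean arterial pulse rides on top with its HbO/HbR
    split set by φ(SpO2), so that per-beat amplitudes satisfy
    PA_HbO/PA_HbR = φ while the pulse in CHbT has the configured depth.
    """
    sc = scenario
    n = int(round(sc.duration_s * sc.fs))
    t = np.arange(n) / sc.fs
    rng = np.random.default_rng(seed)

    pr = sc.pr_at(t)
    rr = sc.rr_at(t)
    spo2 = sc.spo2_at(t)
    sto2 = sc.sto2_at(t)
    phi = sc.coupling.phi_from_spo2(spo2)
    if np.any(phi <= 0):
        raise ValueError("infeasible coupling: non-positive pulse-amplitude ratio")

    chbt0 = sc.baseline.chbt
    # respiratory modulation of the total pool (preserves StO2)
    theta_r = np.cumsum(rr / 60.0) / sc.fs
    pool = chbt0 * (1.0 + sc.respiratory_depth * np.sin(2 * np.pi * theta_r))
    chbo_base = pool * sto2 / 100.0
    chbr_base = pool * (1.0 - sto2 / 100.0)

    # cardiac pulse at the instantaneous rate, zero-mean, unit range
    theta_c = np.cumsum(pr / 60.0) / sc.fs
    w = _pulse_waveform(theta_c)
    if w.max() > w.min():
        w = (w - w.mean()) / (w.max() - w.min())
    else:
        w = np.zeros_like(w)
    pulse_chbt = sc.cardiac_depth * chbt0 * w
    frac_o = phi / (1.0 + phi)
    chbo = chbo_base + frac_o * pulse_chbt
    chbr = chbr_base + (1.0 - frac_o) * pulse_chbt

    if sc.series_noise_sd > 0:
        chbo = chbo + rng.normal(0.0, sc.series_noise_sd, n)
        chbr = chbr + rng.normal(0.0, sc.series_noise_sd, n)
    if np.any(chbo < 0) or np.any(chbr < 0):
        raise ValueError(
            "infeasible scenario: negative hemoglobin concentrations "
            "(modulation depths too large for the baseline)"
        )

    series = ChromoTimeSeries(timestamps=t, chbo=chbo, chbr=chbr, fs=sc.fs)
    truth = pd.DataFrame(
        {
            "time_s": t,
            "pr": pr,
            "rr": rr,
            "spo2": spo2,
            "sto2": sto2,
            "phi": phi,
            "chbo": chbo,
            "chbr": chbr,
        }
    )
    return ScenarioSeries(scenario=sc, series=series, truth=truth, seed=seed)


class ReflectanceEmulator:
    """Fast reflectance evaluation backed by a scattering-only path survey.

    One absorption-free Monte Carlo run per wavelength records the dermal
    path-length distribution of escaping photons (melanin and baseline
    attenuation folded into the photon weights); diffuse reflectance for
    any hemoglobin concentrations then evaluates analytically as
    E[w·exp(−mu_a,hb·L_dermis)].  Every frame reuses the same photon paths,
    so frame-to-frame reflectance differences are smooth — exactly how a
    deterministic tissue behaves.
    """

    def __init__(
        self,
        cm: float,
        skin: SkinModel = SkinModel(),
        photons: int = 200_000,
        seed: int = 123,
        n_bins: int = 512,
    ):
        self.cm = cm
        self.skin = skin
        wl, paths, weights = white_path_survey(
            cm, photons=photons, seed=seed, skin=skin, n_bins=n_bins
        )
        self.wavelengths = wl
        self._paths = paths
        self._weights = weights
        self._k_hbo = spectra.blood_absorption(wl, oxygenated=True)
        self._k_hbr = spectra.blood_absorption(wl, oxygenated=False)

    def reflectance(self, chbo, chbr, chunk: int = 256) -> np.ndarray:
        """Spectra for arrays of concentrations; returns (T, W)."""
        chbo = np.atleast_1d(np.asarray(chbo, dtype=float))
        chbr = np.atleast_1d(np.asarray(chbr, dtype=float))
        out = np.empty((chbo.size, self.wavelengths.size))
        for s in range(0, chbo.size, chunk):
            e = min(s + chunk, chbo.size)
            mu = (
                chbo[s:e, None] * self._k_hbo[None, :]
                + chbr[s:e, None] * self._k_hbr[None, :]
            )  # (c, W)
            att = np.exp(-mu[:, :, None] * self._paths[None, :, :])  # (c, W, B)
            out[s:e] = np.einsum("cwb,wb->cw", att, self._weights)
        return out


@dataclass
class SyntheticCamera:
    """Linear RGB camera: a channel-mixing matrix applied to XYZ, normalized
    so a perfect white reflector maps to (1, 1, 1)."""

    mixing: np.ndarray = field(
        default_factory=lambda: np.array(
            [  # XYZ -> linear sRGB primaries
                [3.2406, -1.5372, -0.4986],
                [-0.9689, 1.8758, 0.0415],
                [0.0557, -0.2040, 1.0570],
            ]
        )
    )
    illuminant: colorimetry.IlluminantSPD | None = None

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.illuminant is None:
            self.illuminant = colorimetry.IlluminantSPD.d65()
        white = _unit_spectrum()
        self._white_rgb = self.mixing @ np.array(
            colorimetry.spectrum_to_xyz(white, self.illuminant)
        )

    def rgb_from_xyz(self, xyz: np.ndarray) -> np.ndarray:
        """White-normalized device RGB for (..., 3) XYZ."""
        arr = np.asarray(xyz, dtype=float)
        return (arr @ self.mixing.T) / self._white_rgb


def _unit_spectrum():
    from .forward_model import ReflectanceSpectrum

    return ReflectanceSpectrum(
        wavelengths=spectra.WAVELENGTHS,
        reflectance=np.ones_like(spectra.WAVELENGTHS),
    )


def make_color_checker(
    camera: SyntheticCamera | None = None, seed: int = 2024
) -> colorimetry.ColorCheckerTable:
    """Synthetic 24-patch calibration table (vendor-style float values).

    Patch reflectances are smooth mixtures of broad Gaussian bands plus six
    neutral (gray) steps, imaged through the synthetic camera.
    """
    camera = camera or SyntheticCamera()
    rng = np.random.default_rng(seed)
    wl = spectra.WAVELENGTHS
    specs = []
    for _ in range(18):
        base = rng.uniform(0.05, 0.25)
        r = np.full_like(wl, base)
        for _ in range(rng.integers(1, 4)):
            center = rng.uniform(420, 680)
            width = rng.uniform(40, 90)
            amp = rng.uniform(0.1, 0.6)
            r = r + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        specs.append(np.clip(r, 0.02, 0.95))
    for level in np.linspace(0.05, 0.9, 6):
        specs.append(np.full_like(wl, level))

    from .forward_model import ReflectanceSpectrum

    rows = []
    spectra_map = {}
    for i, r in enumerate(specs):
        spec = ReflectanceSpectrum(wavelengths=wl, reflectance=r)
        xyz = colorimetry.spectrum_to_xyz(spec, camera.illuminant)
        rgb = camera.rgb_from_xyz(np.array(xyz))
        rows.append(
            {
                "patch_id": i,
                "R": rgb[0],
                "G": rgb[1],
                "B": rgb[2],
                "X": xyz[0],
                "Y": xyz[1],
                "Z": xyz[2],
            }
        )
        spectra_map[i] = r
    return colorimetry.ColorCheckerTable(table=pd.DataFrame(rows), spectra=spectra_map)


def _vignette(shape, strength: float) -> np.ndarray:
    h, w = shape
    rows = (np.arange(h) - (h - 1) / 2) / max((h - 1) / 2, 1)
    cols = (np.arange(w) - (w - 1) / 2) / max((w - 1) / 2, 1)
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    return 1.0 - strength * r2 / 2.0


@dataclass
class RenderedVideo:
    frames: np.ndarray  # (T, H, W, 3) uint8
    diffuser: np.ndarray  # (H, W, 3) uint8
    camera: SyntheticCamera
    checker: colorimetry.ColorCheckerTable
    n_clipped: int
    fs: float


def render_video(
    scenario_series: ScenarioSeries,
    frame_shape: tuple[int, int] = (96, 96),
    seed: int = 0,
    camera: SyntheticCamera | None = None,
    emulator: ReflectanceEmulator | None = None,
    skin: SkinModel = SkinModel(),
    vignette_strength: float = 0.25,
    noise_sd_lsb: float = 1.0,
    gain: float = 0.9,
) -> RenderedVideo:
    """Render a scenario into 8-bit RGB frames plus a diffuser frame.

    Every pixel of a frame shares the frame's chromophore state (the ROI is
    spatially uniform); the vignette and per-pixel sensor noise differ.
    The diffuser frame embeds the same vignette so flat-field correction
    can undo it.  Out-of-range values are clipped and counted in
    ``n_clipped``.
    """
    import warnings

    camera = camera or SyntheticCamera()
    sc = scenario_series.scenario
    if emulator is None:
        emulator = ReflectanceEmulator(cm=sc.baseline.cm, skin=skin)
    refl = emulator.reflectance(
        scenario_series.series.chbo, scenario_series.series.chbr
    )  # (T, W)

    # reflectance spectra -> XYZ (vectorized, Y_white = 100)
    cmf = spectra.color_matching_functions()
    wl = emulator.wavelengths
    s = np.interp(wl, camera.illuminant.wavelengths, camera.illuminant.power)
    bar = np.column_stack(
        [np.interp(wl, cmf["wavelength_nm"], cmf[c]) for c in ("xbar", "ybar", "zbar")]
    )
    k = 100.0 / np.sum(s * bar[:, 1])
    xyz = k * (refl * s[None, :]) @ bar  # (T, 3)
    rgbn = camera.rgb_from_xyz(xyz)  # white-normalized, (T, 3)

    h, w = frame_shape
    vig = _vignette((h, w), vignette_strength)[:, :, None]
    rng = np.random.default_rng(seed)
    n_frames = rgbn.shape[0]
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    n_clipped = 0
    scale = gain * 255.0
    for i in range(n_frames):
        raw = vig * (scale * rgbn[i])[None, None, :]
        if noise_sd_lsb > 0:
            raw = raw + rng.normal(0.0, noise_sd_lsb, raw.shape)
        n_clipped += int(np.sum((raw < 0) | (raw > 255)))
        frames[i] = np.clip(np.round(raw), 0, 255).astype(np.uint8)

    raw_d = vig * (scale * 0.99 * np.ones(3))[None, None, :]
    if noise_sd_lsb > 0:
        raw_d = raw_d + rng.normal(0.0, noise_sd_lsb, raw_d.shape)
    diffuser = np.clip(np.round(raw_d), 0, 255).astype(np.uint8)

    if n_clipped:
        warnings.warn(f"{n_clipped} pixel values clipped to the 8-bit range")
    checker = make_color_checker(camera)
    return RenderedVideo(
        frames=frames,
        diffuser=diffuser,
        camera=camera,
        checker=checker,
        n_clipped=n_clipped,
        fs=sc.fs,
    )


def generate_reference_traces(
    truth: pd.DataFrame,
    noise_sd: float = 0.0,
    bias: float = 0.0,
    seed: int = 0,
    device_fs: float = 1.0,
    columns: tuple[str, ...] = ("pr", "rr", "spo2", "sto2"),
) -> pd.DataFrame:
    """Simulated reference-device readouts: truth + bias + seeded noise,
    resampled at a device-typical rate."""
    rng = np.random.default_rng(seed)
    t = truth["time_s"].to_numpy()
    t_dev = np.arange(t[0], t[-1], 1.0 / device_fs)
    out = {"time_s": t_dev}
    for col in columns:
        vals = np.interp(t_dev, t, truth[col].to_numpy())
        out[col] = vals + bias + rng.normal(0.0, noise_sd, t_dev.size)
    return pd.DataFrame(out)
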