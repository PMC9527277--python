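"""Layered-skin Monte Carlo forward model.

Generates diffuse reflectance spectra of a two-layer skin model (melanotic
epidermis over a hemoglobin-bearing dermis) as a function of chromophore
concentrations, and builds the regression training set that links
chromophore states to camera-space XYZ tristimulus values.

The tissue geometry defaults — 0.06 mm epidermis over a dermis treated as
semi-infinite, a single power-law reduced-scattering spectrum, g = 0.9,
n = 1.4 — are standard skin-optics stand-ins; every parameter is
configurable through :class:`SkinModel`.

Crossed-polarizer acquisition is modeled by omitting the specular term:
photons are launched just below the surface with unit weight, so the
reported reflectance is the diffuse fraction of light entering the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import spectra
from ._mc import run_layered, run_white

__all__ = [
    "LayerOptics",
    "ChromophoreState",
    "ReflectanceSpectrum",
    "ChromophoreRanges",
    "SkinModel",
    "TrainingSet",
    "absorption_from_chromophores",
    "skin_layers",
    "simulate_reflectance",
    "build_training_set",
]


@dataclass
class LayerOptics:
    """Optical properties of one tissue layer on a wavelength grid."""

    thickness: float  # mm
    mu_a: np.ndarray  # 1/mm per wavelength
    mu_s: np.ndarray  # 1/mm per wavelength
    g: float = 0.9
    n: float = 1.4
    semi_infinite: bool = False

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s = np.asarray(self.mu_s, dtype=float)
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ValueError("absorption/scattering coefficients must be >= 0")
        if abs(self.g) > 1:
            raise ValueError("anisotropy g must satisfy |g| <= 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.mu_a.shape != self.mu_s.shape:
            raise ValueError("mu_a and mu_s must share the wavelength grid")


@dataclass(frozen=True)
class ChromophoreState:
    """Scalar chromophore concentrations (volume fractions).

    ``cm`` is the epidermal melanosome fraction; ``chbo``/``chbr`` are the
    dermal blood-volume fractions carried by oxy-/deoxyhemoglobin.
    """

    cm: float
    chbo: float
    chbr: float

    def __post_init__(self) -> None:
        if self.cm < 0 or self.chbo < 0 or self.chbr < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def chbt(self) -> float:
        return self.chbo + self.chbr

    @property
    def sto2(self) -> float:
        """Tissue oxygen saturation in %, NaN when CHbT = 0."""
        if self.chbt == 0:
            return float("nan")
        return 100.0 * self.chbo / self.chbt


@dataclass
class ReflectanceSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    reflectance: np.ndarray  # fraction in [0, 1]
    mc_stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise ValueError("reflectance must lie in [0, 1]")
        if self.mc_stderr is not None:
            self.mc_stderr = np.asarray(self.mc_stderr, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "reflectance": self.reflectance,
                "stderr": self.mc_stderr
                if self.mc_stderr is not None
                else np.full_like(self.reflectance, np.nan),
            }
        )


@dataclass(frozen=True)
class ChromophoreRanges:
    """Sampling ranges for the training set (volume fractions / %)."""

    cm: tuple[float, float] = (0.01, 0.10)
    chbt: tuple[float, float] = (0.002, 0.02)
    sto2: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.cm, self.chbt, self.sto2):
            if not hi > lo:
                raise ValueError("each range must be non-degenerate (hi > lo)")


@dataclass(frozen=True)
class SkinModel:
    """Two-layer skin geometry and scattering configuration.

    Scattering is specified through the reduced coefficient
    mu_s' = a·(λ/500)^-b.  By the similarity relation the default runs use
    isotropic scattering with mu_s = mu_s' (g = 0), which reproduces the
    diffuse reflectance of the anisotropic medium at a fraction of the
    cost; set g = 0.9 for full Henyey–Greenstein runs (mu_s is always
    derived as mu_s'/(1−g)).
    """

    epidermis_thickness: float = 0.06  # mm
    dermis_thickness: float = 10.0  # mm, truncation depth of the semi-infinite dermis
    g: float = 0.0
    n: float = 1.4
    scatter_a: float = 4.6  # mu_s' at 500 nm, 1/mm
    scatter_b: float = 1.3  # scattering power-law exponent
    n_ambient: float = 1.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1


def absorption_from_chromophores(
    state: ChromophoreState, layer_role: str, wavelengths: np.ndarray
) -> np.ndarray:
    """Absorption coefficient (mm^-1) of one skin layer.

    Melanin contributes only to the epidermis, the hemoglobins only to the
    dermis; a bloodless, melanin-free baseline is present in both.
    """
    wl = np.asarray(wavelengths, dtype=float)
    mu_a = spectra.baseline_absorption(wl)
    if layer_role == "epidermis":
        mu_a = mu_a + state.cm * spectra.melanin_absorption(wl)
    elif layer_role == "dermis":
        mu_a = (
            mu_a
            + state.chbo * spectra.blood_absorption(wl, oxygenated=True)
            + state.chbr * spectra.blood_absorption(wl, oxygenated=False)
        )
    else:
        raise ValueError(f"unknown layer role {layer_role!r}")
    return mu_a


def skin_layers(
    state: ChromophoreState,
    wavelengths: np.ndarray | None = None,
    skin: SkinModel = SkinModel(),
) -> list[LayerOptics]:
    """Build the two-layer optics stack for a chromophore state."""
    wl = spectra.WAVELENGTHS if wavelengths is None else np.asarray(wavelengths)
    mu_s = spectra.reduced_scattering(wl, skin.scatter_a, skin.scatter_b) / (
        1.0 - skin.g
    )
    return [
        LayerOptics(
            thickness=skin.epidermis_thickness,
            mu_a=absorption_from_chromophores(state, "epidermis", wl),
            mu_s=mu_s,
            g=skin.g,
            n=skin.n,
        ),
        LayerOptics(
            thickness=skin.dermis_thickness,
            mu_a=absorption_from_chromophores(state, "dermis", wl),
            mu_s=mu_s,
            g=skin.g,
            n=skin.n,
            semi_infinite=True,
        ),
    ]


def _layer_arrays(layers: list[LayerOptics]):
    n_wl = layers[0].mu_a.shape[0]
    for lay in layers:
        if lay.mu_a.shape[0] != n_wl:
            raise ValueError("all layers must share the wavelength grid")
    mu_a = np.stack([lay.mu_a for lay in layers])
    mu_s = np.stack([lay.mu_s for lay in layers])
    g = np.array([lay.g for lay in layers])
    n = np.array([lay.n for lay in layers])
    thick = np.array([lay.thickness for lay in layers])
    semi = layers[-1].semi_infinite
    return mu_a, mu_s, g, n, thick, semi


def simulate_reflectance(
    layers: list[LayerOptics],
    photons: int = 10_000,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    skin: SkinModel = SkinModel(),
    energy_check: bool = True,
) -> ReflectanceSpectrum:
    """Total diffuse reflectance spectrum of a layer stack.

    Wavelengths are simulated independently with ``photons`` each; the
    per-wavelength Monte Carlo standard error is reported alongside.  The
    run is reproducible bit-for-bit for a given seed.
    """
    if photons < 1_000:
        raise ValueError("photons must be >= 1000")
    if not layers:
        raise ValueError("at least one layer is required")
    mu_a, mu_s, g, n, thick, semi = _layer_arrays(layers)
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else spectra.WAVELENGTHS[: mu_a.shape[1]]
    )
    n_wl = mu_a.shape[1]
    refl = np.empty(n_wl)
    stderr = np.empty(n_wl)
    for k in range(n_wl):
        r, t, a, r_sq = run_layered(
            np.ascontiguousarray(mu_a[:, k]),
            np.ascontiguousarray(mu_s[:, k]),
            g,
            n,
            thick,
            skin.n_ambient,
            semi,
            photons,
            np.uint64(seed * 1_000_003 + k),
            skin.roulette_threshold,
            skin.roulette_survival,
        )
        if energy_check:
            total = r + t + a
            if abs(total - 1.0) > 1e-6:
                raise RuntimeError(
                    f"photon weight not conserved at index {k}: {total!r}"
                )
        refl[k] = r
        stderr[k] = np.sqrt(max(0.0, (r_sq - r * r)) / photons)
    return ReflectanceSpectrum(wavelengths=wl, reflectance=refl, mc_stderr=stderr)


@dataclass
class TrainingSet:
    """Paired (chromophore state, XYZ) samples plus generation metadata."""

    table: pd.DataFrame  # columns Cm, CHbO, CHbR, X, Y, Z
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["Cm", "CHbO", "CHbR", "X", "Y", "Z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"training table missing columns {missing}")
        states = self.table[["Cm", "CHbO", "CHbR"]]
        if states.duplicated().any():
            raise ValueError("duplicate chromophore states in training set")

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.table.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.metadata, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        table = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(table=table, metadata=meta)


def sample_states(
    ranges: ChromophoreRanges, n: int, seed: int
) -> list[ChromophoreState]:
    """Latin-hypercube sample of chromophore states.

    Sampling is done in (Cm, CHbT, StO2) space so that total blood volume
    and oxygenation are independently stratified; CHbO/CHbR are derived.
    """
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    u = sampler.random(n)
    lo = np.array([ranges.cm[0], ranges.chbt[0], ranges.sto2[0]])
    hi = np.array([ranges.cm[1], ranges.chbt[1], ranges.sto2[1]])
    x = qmc.scale(u, lo, hi)
    states = []
    for cm, chbt, sto2 in x:
        states.append(
            ChromophoreState(
                cm=float(cm),
                chbo=float(chbt * sto2 / 100.0),
                chbr=float(chbt * (1.0 - sto2 / 100.0)),
            )
        )
    return states


def build_training_set(
    ranges: ChromophoreRanges = ChromophoreRanges(),
    n: int = 300,
    photons: int = 10_000,
    seed: int = 0,
    skin: SkinModel = SkinModel(),
    illuminant: "pd.DataFrame | None" = None,
) -> TrainingSet:
    """Simulate ``n`` chromophore states and record their XYZ values.

    Each state's diffuse reflectance spectrum (400–700 nm, 10 nm steps) is
    produced by the Monte Carlo model and converted to XYZ under the
    configured illuminant (D65 by default).
    """
    from . import colorimetry

    if n < 20:
        raise ValueError(
            "n must be >= 20: the 10-predictor quadratic regression would be "
            "rank-deficient on fewer samples"
        )
    states = sample_states(ranges, n, seed)
    illum = colorimetry.IlluminantSPD.d65() if illuminant is None else illuminant
    rows = []
    for i, st in enumerate(states):
        spec = simulate_reflectance(
            skin_layers(st, skin=skin),
            photons=photons,
            seed=seed * 7_919 + i,
            skin=skin,
        )
        x, y, z = colorimetry.spectrum_to_xyz(spec, illum)
        rows.append(
            {
                "Cm": st.cm,
                "CHbO": st.chbo,
                "CHbR": st.chbr,
                "X": x,
                "Y": y,
                "Z": z,
            }
        )
    meta = {
        "seed": seed,
        "photons": photons,
        "n": n,
        "ranges": {
            "cm": list(ranges.cm),
            "chbt": list(ranges.chbt),
            "sto2": list(ranges.sto2),
        },
        "skin": asdict(skin),
    }
    return TrainingSet(table=pd.DataFrame(rows), metadata=meta)


def white_path_survey(
    state_cm: float,
    photons: int = 50_000,
    seed: int = 0,
    skin: SkinModel = SkinModel(),
    wavelengths: np.ndarray | None = None,
    n_bins: int = 512,
):
    """Scattering-only path-length survey for fast reflectance evaluation.

    Runs one absorption-free Monte Carlo walk per wavelength and compresses
    the escaping photons' dermal path lengths into weighted bins, folding
    the (fixed) epidermal melanin attenuation into the bin weights.  The
    reflectance for any dermal absorption mu_a(lambda) then evaluates as
    sum_b w_b * exp(-mu_a * L_b), which is what
    :class:`camvitals.synthetic.ReflectanceEmulator` uses to render video
    frames without rerunning the transport.

    Returns (wavelengths, bin_paths, bin_weights) with shapes (W,), (W, B),
    (W, B).
    """
    wl = spectra.WAVELENGTHS if wavelengths is None else np.asarray(wavelengths)
    epi_state = ChromophoreState(cm=state_cm, chbo=0.0, chbr=0.0)
    mu_a_epi = absorption_from_chromophores(epi_state, "epidermis", wl)
    mu_a_base = spectra.baseline_absorption(wl)
    mu_s = spectra.reduced_scattering(wl, skin.scatter_a, skin.scatter_b) / (
        1.0 - skin.g
    )
    g = np.array([skin.g, skin.g])
    n_l = np.array([skin.n, skin.n])
    thick = np.array([skin.epidermis_thickness, skin.dermis_thickness])

    bin_paths = np.zeros((wl.size, n_bins))
    bin_weights = np.zeros((wl.size, n_bins))
    for k in range(wl.size):
        mus_k = np.array([mu_s[k], mu_s[k]])
        paths, n_esc = run_white(
            mus_k, g, n_l, thick, skin.n_ambient, photons, np.uint64(seed * 1_000_003 + k)
        )
        if n_esc == 0:
            continue
        l_epi = paths[:n_esc, 0]
        l_derm = paths[:n_esc, 1]
        # epidermal melanin + both layers' baseline folded into the weight
        w = np.exp(-mu_a_epi[k] * l_epi - mu_a_base[k] * l_derm) / photons
        # log-spaced dermal path bins
        lmax = max(l_derm.max(), 1e-6)
        edges = np.concatenate(
            [[0.0], np.geomspace(1e-3, lmax + 1e-9, n_bins)]
        )
        idx = np.clip(np.searchsorted(edges, l_derm, side="right") - 1, 0, n_bins - 1)
        wsum = np.bincount(idx, weights=w, minlength=n_bins)
        lsum = np.bincount(idx, weights=w * l_derm, minlength=n_bins)
        nz = wsum > 0
        bin_weights[k] = wsum
        bin_paths[k, nz] = lsum[nz] / wsum[nz]
    return wl, bin_paths, bin_weights
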