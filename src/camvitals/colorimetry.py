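"""Reflectance→XYZ conversion and camera calibration (matrix M1).

XYZ values follow the CIE 1931 2° observer with the normalization constant
chosen so a perfect reflector has Y = 100 under the working illuminant.
The camera model is a single affine map (1, R, G, B) → (X, Y, Z), fitted by
ordinary least squares from a 24-patch color-checker table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from . import spectra

__all__ = [
    "IlluminantSPD",
    "M1Transform",
    "ColorCheckerTable",
    "spectrum_to_xyz",
    "fit_m1",
    "rgb_to_xyz",
]


@dataclass
class IlluminantSPD:
    wavelengths: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if self.wavelengths[0] > 400 or self.wavelengths[-1] < 700:
            raise ValueError("illuminant must cover 400–700 nm")

    @classmethod
    def d65(cls) -> "IlluminantSPD":
        tab = spectra.illuminant_d65()
        return cls(tab["wavelength_nm"].to_numpy(), tab["relative_power"].to_numpy())


def spectrum_to_xyz(spectrum, illuminant: IlluminantSPD | None = None):
    """CIE XYZ of a reflectance spectrum under an illuminant.

    X, Y, Z = k * sum(R(l) * S(l) * cmf(l) * dl) with k set so a unit
    (perfect) reflector has Y = 100.  ``spectrum`` may be a
    ReflectanceSpectrum or any object with ``wavelengths``/``reflectance``.
    """
    illum = IlluminantSPD.d65() if illuminant is None else illuminant
    wl = np.asarray(spectrum.wavelengths, dtype=float)
    refl = np.asarray(spectrum.reflectance, dtype=float)
    lo = max(wl[0], illum.wavelengths[0], spectra.WAVELENGTHS[0])
    hi = min(wl[-1], illum.wavelengths[-1], spectra.WAVELENGTHS[-1])
    if hi <= lo:
        raise ValueError("spectrum and illuminant have no common wavelength support")
    grid = spectra.WAVELENGTHS[(spectra.WAVELENGTHS >= lo) & (spectra.WAVELENGTHS <= hi)]
    r = np.interp(grid, wl, refl)
    s = np.interp(grid, illum.wavelengths, illum.power)
    cmf = spectra.color_matching_functions()
    xbar = np.interp(grid, cmf["wavelength_nm"], cmf["xbar"])
    ybar = np.interp(grid, cmf["wavelength_nm"], cmf["ybar"])
    zbar = np.interp(grid, cmf["wavelength_nm"], cmf["zbar"])
    k = 100.0 / np.sum(s * ybar)
    x = k * np.sum(r * s * xbar)
    y = k * np.sum(r * s * ybar)
    z = k * np.sum(r * s * zbar)
    return float(x), float(y), float(z)


@dataclass
class M1Transform:
    """3×4 affine camera matrix mapping (1, R, G, B) → (X, Y, Z)."""

    matrix: np.ndarray  # shape (3, 4); rows X, Y, Z
    residuals: np.ndarray | None = None  # per-patch RMS residual
    n_patches: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 4):
            raise ValueError("M1 must be 3x4")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("M1 coefficients must be finite")

    def to_json(self, path) -> None:
        payload = {
            "matrix": self.matrix.tolist(),
            "residuals": None
            if self.residuals is None
            else np.asarray(self.residuals).tolist(),
            "n_patches": self.n_patches,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "M1Transform":
        with open(path) as fh:
            payload = json.load(fh)
        res = payload.get("residuals")
        return cls(
            matrix=np.asarray(payload["matrix"]),
            residuals=None if res is None else np.asarray(res),
            n_patches=payload.get("n_patches", 0),
        )


@dataclass
class ColorCheckerTable:
    """24-patch calibration table: device RGB plus reference XYZ."""

    table: pd.DataFrame  # columns patch_id, R, G, B, X, Y, Z
    spectra: dict = field(default_factory=dict)  # patch_id -> reflectance array

    def __post_init__(self) -> None:
        required = ["patch_id", "R", "G", "B", "X", "Y", "Z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"checker table missing columns {missing}")
        if len(self.table) != 24:
            raise ValueError("a color checker table has exactly 24 patches")
        if (self.table[["X", "Y", "Z"]] < 0).any().any():
            raise ValueError("reference XYZ must be non-negative")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ColorCheckerTable":
        return cls(table=pd.read_csv(path))


def fit_m1(table: ColorCheckerTable | pd.DataFrame) -> M1Transform:
    """Least-squares fit of the affine RGB→XYZ map from checker patches."""
    df = table.table if isinstance(table, ColorCheckerTable) else table
    df = df.dropna(subset=["R", "G", "B", "X", "Y", "Z"])
    if len(df) < 10:
        raise ValueError("need at least 10 patches with both RGB and XYZ")
    design = np.column_stack(
        [np.ones(len(df)), df["R"].to_numpy(), df["G"].to_numpy(), df["B"].to_numpy()]
    )
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError(
            "rank-deficient checker table: RGB values do not span 3 dimensions"
        )
    target = df[["X", "Y", "Z"]].to_numpy()
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    pred = design @ coef
    residuals = np.sqrt(np.mean((pred - target) ** 2, axis=1))
    return M1Transform(matrix=coef.T, residuals=residuals, n_patches=len(df))


def rgb_to_xyz(rgb, m1: M1Transform):
    """Apply M1 to an RGB triple or an (..., 3) image; shape is preserved."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 RGB channels")
    flat = arr.reshape(-1, 3)
    design = np.column_stack([np.ones(len(flat)), flat])
    out = design @ m1.matrix.T
    return out.reshape(arr.shape)
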