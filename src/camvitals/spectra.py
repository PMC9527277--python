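"""Bundled spectral constants and chromophore absorption builders.

All spectral tables are tabulated on the working grid 400–700 nm at 10 nm
steps.  Absorption coefficients are expressed in mm^-1; concentrations are
dimensionless volume fractions:

* ``Cm``   — epidermal melanosome volume fraction (0.05 = 5 %),
* ``CHbO`` / ``CHbR`` — dermal whole-blood volume fraction carried by
  oxygenated / deoxygenated hemoglobin, assuming 150 g/L hemoglobin in
  whole blood.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

#: working wavelength grid (nm)
WAVELENGTHS = np.arange(400.0, 701.0, 10.0)

#: hemoglobin concentration of whole blood, mol/L (150 g/L / 64500 g/mol)
BLOOD_HB_MOLARITY = 150.0 / 64500.0

_LN10 = np.log(10.0)


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("camvitals.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def color_matching_functions() -> pd.DataFrame:
    """CIE 1931 2° standard observer (x̄, ȳ, z̄), 10 nm tabulation."""
    return _load_table("cie_1931_2deg_10nm.csv")


@lru_cache(maxsize=None)
def illuminant_d65() -> pd.DataFrame:
    """CIE D65 relative spectral power distribution, 10 nm tabulation."""
    return _load_table("illuminant_d65_10nm.csv")


@lru_cache(maxsize=None)
def hemoglobin_extinction() -> pd.DataFrame:
    """Molar extinction of HbO2 / HbR in cm^-1/M (decadic)."""
    return _load_table("hemoglobin_extinction_10nm.csv")


def _check_support(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < WAVELENGTHS[0] or wl.max() > WAVELENGTHS[-1]:
        raise ValueError(
            f"wavelengths must lie within [{WAVELENGTHS[0]:.0f}, "
            f"{WAVELENGTHS[-1]:.0f}] nm, got [{wl.min()}, {wl.max()}]"
        )
    return wl


def blood_absorption(wavelengths: np.ndarray, oxygenated: bool) -> np.ndarray:
    """Absorption coefficient (mm^-1) of whole blood per unit volume fraction.

    mu_a = ln(10) * eps(lambda) * C_Hb,blood, converted from cm^-1 to mm^-1.
    """
    wl = _check_support(wavelengths)
    tab = hemoglobin_extinction()
    col = "eps_hbo2_cm1_M" if oxygenated else "eps_hbr_cm1_M"
    eps = np.interp(wl, tab["wavelength_nm"], tab[col])
    return _LN10 * eps * BLOOD_HB_MOLARITY * 0.1


def melanin_absorption(wavelengths: np.ndarray) -> np.ndarray:
    """Absorption (mm^-1) of melanosome interior per unit volume fraction.

    Power-law fit mu_a = 6.6e11 * lambda^-3.33 cm^-1 widely used for
    epidermal melanin.
    """
    wl = _check_support(wavelengths)
    return 6.6e11 * wl**-3.33 * 0.1


def baseline_absorption(wavelengths: np.ndarray) -> np.ndarray:
    """Bloodless, melanin-free skin baseline absorption (mm^-1)."""
    wl = _check_support(wavelengths)
    return (0.0244 + 8.53 * np.exp(-(wl - 154.0) / 66.2)) * 0.1


def reduced_scattering(
    wavelengths: np.ndarray, a: float = 4.6, b: float = 1.3
) -> np.ndarray:
    """Typical skin reduced scattering mu_s' = a*(lambda/500)^-b (mm^-1)."""
    wl = _check_support(wavelengths)
    return a * (wl / 500.0) ** -b


def isosbestic_wavelength() -> float:
    """Grid wavelength where |eps_HbO2 - eps_HbR| is smallest."""
    tab = hemoglobin_extinction()
    diff = np.abs(tab["eps_hbo2_cm1_M"] - tab["eps_hbr_cm1_M"]).to_numpy()
    return float(tab["wavelength_nm"].iloc[int(np.argmin(diff))])
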