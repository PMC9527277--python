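"""Inverse mapping from XYZ to chromophore concentrations (matrix M2).

A second-order multiple regression per chromophore:

    C = c0 + c1 X + c2 Y + c3 Z + c4 X^2 + c5 Y^2 + c6 Z^2
        + c7 XY + c8 XZ + c9 YZ

fitted by ordinary least squares on the Monte-Carlo training set.  The
three coefficient vectors (melanin, HbO, HbR) stack into the 10×3 matrix
M2.  Predictors are deliberately not standardized so the coefficients slot
into M2 exactly as the feature order above lays out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

__all__ = [
    "M2Transform",
    "ChromophoreMaps",
    "expand_features",
    "fit_m2",
    "estimate_concentrations",
    "hemoglobin_summaries",
]

_FEATURE_NAMES_2 = ["1", "X", "Y", "Z", "X^2", "Y^2", "Z^2", "XY", "XZ", "YZ"]
_TARGETS = ["Cm", "CHbO", "CHbR"]


def expand_features(xyz, order: int = 2) -> np.ndarray:
    """Polynomial predictor vector(s) for XYZ triples.

    Order 1 gives (1, X, Y, Z); order 2 appends the squares and the three
    cross terms, in exactly the sequence (1, X, Y, Z, X², Y², Z², XY, XZ, YZ).
    Accepts a triple or an (..., 3) array; returns (..., n_features).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    arr = np.asarray(xyz, dtype=float)
    scalar_input = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if pts.shape[-1] != 3:
        raise ValueError("last axis must hold (X, Y, Z)")
    flat = pts.reshape(-1, 3)
    x, y, z = flat[:, 0], flat[:, 1], flat[:, 2]
    cols = [np.ones_like(x), x, y, z]
    if order == 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    out = np.column_stack(cols)
    if scalar_input:
        return out[0]
    return out.reshape(pts.shape[:-1] + (out.shape[-1],))


@dataclass
class M2Transform:
    """Regression coefficients per chromophore plus fit metadata."""

    coefficients: np.ndarray  # shape (n_features, 3); columns Cm, CHbO, CHbR
    order: int = 2
    r_squared: dict = field(default_factory=dict)  # per target
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_feat = 10 if self.order == 2 else 4
        if self.coefficients.shape != (n_feat, 3):
            raise ValueError(
                f"order-{self.order} M2 must have shape ({n_feat}, 3), "
                f"got {self.coefficients.shape}"
            )

    def to_json(self, path) -> None:
        payload = {
            "order": self.order,
            "targets": _TARGETS,
            "coefficients": {
                t: self.coefficients[:, j].tolist() for j, t in enumerate(_TARGETS)
            },
            "r_squared": self.r_squared,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "M2Transform":
        with open(path) as fh:
            payload = json.load(fh)
        coef = np.column_stack([payload["coefficients"][t] for t in _TARGETS])
        return cls(
            coefficients=coef,
            order=payload["order"],
            r_squared=payload.get("r_squared", {}),
            metadata=payload.get("metadata", {}),
        )


def fit_m2(training, order: int = 2) -> M2Transform:
    """Ordinary least-squares fit of the XYZ→concentration regressions.

    ``training`` is a TrainingSet or a DataFrame with columns
    Cm, CHbO, CHbR, X, Y, Z.  In-sample R² is reported per target and, for
    order 2, asserted against its order-1 counterpart (nested models can
    never fit worse).
    """
    df = training.table if hasattr(training, "table") else training
    n_feat = 10 if order == 2 else 4
    if len(df) <= n_feat:
        raise ValueError(
            f"training size {len(df)} must exceed {n_feat} predictors"
        )
    design = expand_features(df[["X", "Y", "Z"]].to_numpy(), order=order)
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        # identify offending columns by near-zero variance or duplication
        names = _FEATURE_NAMES_2[:n_feat]
        raise ValueError(
            "collinear design matrix; check predictors "
            + ", ".join(names[1:])
        )
    targets = df[_TARGETS].to_numpy()
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    pred = design @ coef
    ss_res = np.sum((targets - pred) ** 2, axis=0)
    ss_tot = np.sum((targets - targets.mean(axis=0)) ** 2, axis=0)
    r2 = {t: float(1.0 - ss_res[j] / ss_tot[j]) for j, t in enumerate(_TARGETS)}
    meta = dict(getattr(training, "metadata", {}))
    meta["n_samples"] = len(df)
    return M2Transform(coefficients=coef, order=order, r_squared=r2, metadata=meta)


@dataclass
class ChromophoreMaps:
    """Per-pixel chromophore estimates with derived CHbT/StO2.

    Negative raw predictions are preserved in cm/chbo/chbr and counted in
    ``n_negative``; StO2 is computed from zero-clamped hemoglobin values and
    flagged NaN where clamped CHbT is 0.
    """

    cm: np.ndarray
    chbo: np.ndarray
    chbr: np.ndarray
    n_negative: int = 0

    @property
    def chbt(self) -> np.ndarray:
        return self.chbo + self.chbr

    @property
    def sto2(self) -> np.ndarray:
        chbo = np.clip(self.chbo, 0.0, None)
        chbr = np.clip(self.chbr, 0.0, None)
        chbt = chbo + chbr
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(chbt > 0, 100.0 * chbo / np.where(chbt > 0, chbt, 1.0), np.nan)
        return out


def estimate_concentrations(xyz, m2: M2Transform) -> ChromophoreMaps:
    """Evaluate the M2 polynomial per pixel (or for a single triple)."""
    arr = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("XYZ input contains non-finite values")
    feats = expand_features(arr, order=m2.order)
    pred = feats @ m2.coefficients
    cm = pred[..., 0]
    chbo = pred[..., 1]
    chbr = pred[..., 2]
    n_neg = int(np.sum(chbo < 0) + np.sum(chbr < 0) + np.sum(cm < 0))
    return ChromophoreMaps(cm=cm, chbo=chbo, chbr=chbr, n_negative=n_neg)


def hemoglobin_summaries(chbo, chbr):
    """Elementwise (CHbT, StO2%); StO2 is NaN wherever CHbT <= 0."""
    chbo = np.asarray(chbo, dtype=float)
    chbr = np.asarray(chbr, dtype=float)
    chbt = chbo + chbr
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(chbt > 0, 100.0 * chbo / np.where(chbt > 0, chbt, 1.0), np.nan)
    return chbt, sto2
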