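"""Method-comparison statistics: Bland–Altman, RMSE, Pearson correlation.

Conventions: differences are estimate − reference; the precision is the
sample SD (n−1) of the differences; limits of agreement are bias ± 2·SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "align_series",
    "bland_altman",
    "rmse",
    "pearson_r",
]


@dataclass
class PairedSeries:
    """Aligned (estimate, reference) pairs for one vital sign."""

    estimate: np.ndarray
    reference: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.estimate.shape != self.reference.shape:
            raise ValueError("estimate and reference must have equal length")
        if not (np.all(np.isfinite(self.estimate)) and np.all(np.isfinite(self.reference))):
            raise ValueError("paired series must be finite")

    def __len__(self) -> int:
        return len(self.estimate)


def align_series(
    est_times,
    est_values,
    ref_times,
    ref_values,
    max_lag: float,
    units: str = "",
) -> tuple[PairedSeries, int]:
    """Nearest-neighbour temporal matching of estimate and reference series.

    Each estimate window is matched to the closest reference sample within
    ``max_lag`` seconds; unmatched or non-finite rows are dropped.  Returns
    the paired series and the number of dropped estimates.
    """
    est_times = np.asarray(est_times, dtype=float)
    est_values = np.asarray(est_values, dtype=float)
    ref_times = np.asarray(ref_times, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    order = np.argsort(ref_times)
    ref_times, ref_values = ref_times[order], ref_values[order]
    pos = np.searchsorted(ref_times, est_times)
    pos = np.clip(pos, 1, len(ref_times) - 1)
    left = pos - 1
    choose_right = np.abs(ref_times[pos] - est_times) < np.abs(
        ref_times[left] - est_times
    )
    idx = np.where(choose_right, pos, left)
    lag = np.abs(ref_times[idx] - est_times)
    ok = (lag <= max_lag) & np.isfinite(est_values) & np.isfinite(ref_values[idx])
    dropped = int(len(est_times) - ok.sum())
    return (
        PairedSeries(estimate=est_values[ok], reference=ref_values[idx][ok], units=units),
        dropped,
    )


@dataclass
class BlandAltmanResult:
    bias: float
    precision_sd: float
    loa_low: float
    loa_high: float
    n: int
    scatter: pd.DataFrame  # per-pair (mean, difference)


def bland_altman(pairs: PairedSeries) -> BlandAltmanResult:
    """Mean bias, precision SD and limits of agreement (bias ± 2·SD)."""
    if len(pairs) < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    diff = pairs.estimate - pairs.reference
    mean = 0.5 * (pairs.estimate + pairs.reference)
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    result = BlandAltmanResult(
        bias=bias,
        precision_sd=sd,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
        n=len(pairs),
        scatter=pd.DataFrame({"mean": mean, "difference": diff}),
    )
    # structural identity, asserted on every call
    assert np.isclose(result.loa_high - result.loa_low, 4.0 * sd)
    return result


def rmse(pairs: PairedSeries) -> float:
    """Root mean squared difference between estimate and reference."""
    if len(pairs) < 1:
        raise ValueError("rmse needs at least 1 pair")
    return float(np.sqrt(np.mean((pairs.estimate - pairs.reference) ** 2)))


def pearson_r(pairs: PairedSeries) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided t-distribution p-value.

    Returns (NaN, NaN) when either side has zero variance (flagged
    undefined rather than propagating a divide-by-zero).
    """
    if len(pairs) < 3:
        raise ValueError("pearson_r needs at least 3 pairs")
    if np.std(pairs.estimate) == 0 or np.std(pairs.reference) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(pairs.estimate, pairs.reference)
    return float(r), float(p)
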