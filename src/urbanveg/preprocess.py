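"""Deseasonalization, monthly climatologies/thresholds, and pixel screening.

All monthly-series utilities accept either a 1-D series of length
12*years or an array whose leading axis is time; climatologies are
computed per calendar month over the full record (in-sample baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CROPLAND_CUTOFF = 0.50  # pixels with >= 50% cropland cover are excluded


@dataclass
class MonthlyClimatology:
    """Per-calendar-month mean and (optionally) an upper-quantile threshold."""

    mean: np.ndarray  # (12, ...) monthly means
    threshold: np.ndarray | None  # (12, ...) q-quantile, temperature only
    n_years: int
    q: float | None = None


@dataclass
class PixelScreen:
    keep: np.ndarray  # boolean, pixel grid shape
    reason: np.ndarray  # '' for kept pixels, else primary exclusion reason


def _check_series(series: np.ndarray, years: int) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] != 12 * years:
        raise ValueError(f"series length {arr.shape[0]} != 12 * {years} years")
    if years < 2:
        raise ValueError("need years >= 2")
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported; gap-fill upstream")
    return arr


def _by_month(arr: np.ndarray) -> np.ndarray:
    """Reshape (12*Y, ...) -> (Y, 12, ...)."""
    return arr.reshape(-1, 12, *arr.shape[1:])


def deseasonalize(series: np.ndarray, years: int) -> tuple[np.ndarray, MonthlyClimatology]:
    """Remove the mean seasonal cycle: anomaly[t] = x[t] - mean(calendar month of t)."""
    arr = _check_series(series, years)
    monthly = _by_month(arr)
    clim = monthly.mean(axis=0)  # (12, ...)
    anom = (monthly - clim[None]).reshape(arr.shape)
    return anom, MonthlyClimatology(mean=clim, threshold=None, n_years=years)


def percentile_thresholds(series: np.ndarray, years: int, q: float = 0.90) -> MonthlyClimatology:
    """Per-calendar-month empirical q-quantile across years (linear interpolation)."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    arr = _check_series(series, years)
    monthly = _by_month(arr)
    thr = np.quantile(monthly, q, axis=0, method="linear")
    return MonthlyClimatology(mean=monthly.mean(axis=0), threshold=thr, n_years=years, q=q)


def screen_pixels(
    cropland_frac: np.ndarray,
    evi_baseline: np.ndarray,
    user_mask: np.ndarray | None = None,
) -> PixelScreen:
    """Drop pixels with >= 50% cropland, a non-positive rebased EVI baseline,
    or an explicit user mask (mask True = drop).  One primary reason per
    excluded pixel, in that priority order (user mask first)."""
    cropland = np.asarray(cropland_frac, dtype=float)
    baseline = np.asarray(evi_baseline, dtype=float)
    reason = np.full(cropland.shape, "", dtype=object)
    if user_mask is not None:
        reason[np.asarray(user_mask, dtype=bool)] = "user_mask"
    reason[(reason == "") & (cropland >= CROPLAND_CUTOFF)] = "cropland"
    reason[(reason == "") & (baseline <= 0.0)] = "nonpositive_baseline"
    keep = reason == ""
    if not keep.any():
        logger.warning("pixel screen excluded every pixel (%d total)", keep.size)
    return PixelScreen(keep=keep, reason=reason)


def climatology_frame(clim: MonthlyClimatology) -> pd.DataFrame:
    """Flat CSV-ready view of a (possibly per-pixel) climatology."""
    rows = []
    for m in range(12):
        mean = np.atleast_1d(clim.mean[m]).ravel()
        thr = (
            np.atleast_1d(clim.threshold[m]).ravel()
            if clim.threshold is not None
            else np.full(mean.shape, np.nan)
        )
        for pix, (mu, th) in enumerate(zip(mean, thr)):
            rows.append({"month": m + 1, "pixel": pix, "mean": mu, "threshold": th})
    return pd.DataFrame(rows)
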