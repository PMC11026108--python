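"""Resistance and recovery metrics per pixel per hot event.

Both metrics share the bounded form

    metric = 2 * (x - EVIpre) / (EVIpre + |x - EVIpre|)

with x = the in-event EVI of maximum absolute change for resistance, and
x = the mean EVI of the 3 post-event months for recovery.  The metric is
zero when x equals the pre-event baseline, has the sign of the change,
and is confined to (-2, 2) for any positive baseline.

EVI enters rebased: deseasonalized anomalies plus the pixel long-term
mean, so anomaly differences are preserved while the denominator keeps a
positive vegetation level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import HotEvent

PRE_WINDOW = 3  # months immediately before event start
POST_WINDOW = 3  # months immediately after event end


@dataclass
class MetricResult:
    value: float
    evi_pre: float
    evi_x: float  # EVIin for resistance, EVIpost for recovery
    valid: bool
    reason: str = ""


def rebase_evi(anomalies: np.ndarray, long_term_mean) -> np.ndarray:
    """anomaly + long-term mean; preserves anomaly differences exactly."""
    return np.asarray(anomalies, dtype=float) + long_term_mean


def _metric(evi_pre: float, x: float) -> float:
    return 2.0 * (x - evi_pre) / (evi_pre + abs(x - evi_pre))


def compute_resistance(pre_window: np.ndarray, in_window: np.ndarray) -> MetricResult:
    """EVIpre = mean(pre window); EVIin = in-window value of maximum |change|
    (earliest month on ties); metric per the bounded ratio above."""
    pre = np.asarray(pre_window, dtype=float)
    inw = np.asarray(in_window, dtype=float)
    if pre.size == 0 or inw.size == 0:
        raise ValueError("pre and in windows must be non-empty")
    evi_pre = float(pre.mean())
    if evi_pre <= 0.0:
        return MetricResult(np.nan, evi_pre, np.nan, False, "nonpositive_baseline")
    evi_in = float(inw[int(np.argmax(np.abs(inw - evi_pre)))])
    return MetricResult(_metric(evi_pre, evi_in), evi_pre, evi_in, True)


def compute_recovery(pre_window: np.ndarray, post_window: np.ndarray) -> MetricResult:
    """EVIpost = mean of the 3 post-event months; same bounded ratio."""
    pre = np.asarray(pre_window, dtype=float)
    post = np.asarray(post_window, dtype=float)
    if pre.size == 0:
        raise ValueError("pre window must be non-empty")
    if post.size != POST_WINDOW:
        return MetricResult(np.nan, np.nan, np.nan, False, "truncated_post")
    evi_pre = float(pre.mean())
    if evi_pre <= 0.0:
        return MetricResult(np.nan, evi_pre, np.nan, False, "nonpositive_baseline")
    evi_post = float(post.mean())
    return MetricResult(_metric(evi_pre, evi_post), evi_pre, evi_post, True)


def compute_records(
    rebased: np.ndarray,
    events: list[HotEvent],
    pre_window: int = PRE_WINDOW,
    post_window: int = POST_WINDOW,
    pixel_keep: np.ndarray | None = None,
    pixel_area: np.ndarray | None = None,
    city_id: str = "",
    dataset_id: str = "",
) -> pd.DataFrame:
    """Per-pixel-per-event resilience records.

    Parameters
    ----------
    rebased : (T, n_pixels) rebased EVI (anomaly + long-term mean).
    events : characterized hot events on this record.
    pixel_keep : boolean screen; dropped pixels get no rows.
    pixel_area : per-pixel 'urban' / 'rural' / '' labels.

    Records with a truncated pre window are invalid (reason
    ``truncated_pre``); recovery with fewer than ``post_window`` months in
    the record is invalid (``truncated_post``).  A following event starting
    inside the post window sets ``overlap`` but the value is still computed.
    """
    rebased = np.asarray(rebased, dtype=float)
    T, n_pix = rebased.shape
    keep = np.ones(n_pix, dtype=bool) if pixel_keep is None else np.asarray(pixel_keep).ravel()
    area = (
        np.full(n_pix, "", dtype=object) if pixel_area is None else np.asarray(pixel_area).ravel()
    )
    starts = np.array([ev.start for ev in events])
    rows = []
    for ev_idx, ev in enumerate(events):
        pre_lo = ev.start - pre_window
        pre_ok = pre_lo >= 0
        post_hi = ev.end + 1 + post_window
        post_ok = post_hi <= T
        overlap = bool(np.any((starts > ev.end) & (starts <= ev.end + post_window)))
        for p in np.flatnonzero(keep):
            base = {
                "city": city_id,
                "dataset": dataset_id,
                "pixel": int(p),
                "area": area[p],
                "event": ev_idx,
                "season": ev.season,
                "duration": ev.duration,
                "intensity": ev.intensity,
                "overlap": overlap,
            }
            if not pre_ok:
                rows.append(
                    {**base, "evi_pre": np.nan, "evi_in": np.nan, "evi_post": np.nan,
                     "resistance": np.nan, "recovery": np.nan,
                     "valid_resistance": False, "valid_recovery": False,
                     "reason": "truncated_pre"}
                )
                continue
            pre = rebased[pre_lo : ev.start, p]
            res = compute_resistance(pre, rebased[ev.start : ev.end + 1, p])
            rec = compute_recovery(pre, rebased[ev.end + 1 : post_hi, p] if post_ok else rebased[ev.end + 1 :, p])
            rows.append(
                {**base,
                 "evi_pre": res.evi_pre,
                 "evi_in": res.evi_x,
                 "evi_post": rec.evi_x,
                 "resistance": res.value,
                 "recovery": rec.value,
                 "valid_resistance": res.valid,
                 "valid_recovery": rec.valid,
                 "reason": res.reason or rec.reason}
            )
    cols = ["city", "dataset", "pixel", "area", "event", "season", "duration",
            "intensity", "overlap", "evi_pre", "evi_in", "evi_post",
            "resistance", "recovery", "valid_resistance", "valid_recovery", "reason"]
    return pd.DataFrame(rows, columns=cols)
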