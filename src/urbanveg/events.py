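"""Hot-month flagging, event building (merge + concatenation) and characterization.

A month is "hot" when its mean temperature strictly exceeds the
month-specific 90th-percentile threshold.  Runs of hot months form
events; events separated by fewer than ``gap_concat`` non-hot months are
concatenated into a single span (gap months included), applied
left-to-right until all remaining gaps are >= gap_concat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MonthlyClimatology, percentile_thresholds

SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}

DURATION_STRATUM_MONTHS = 4  # long: duration >= 4 months
INTENSITY_STRATUM_DEGC = 2.0  # intense: intensity >= 2 degC


@dataclass
class HotEvent:
    start: int  # 0-based month index, inclusive
    end: int  # inclusive
    city_id: str = ""
    dataset_id: str = ""
    intensity: float = np.nan  # mean exceedance over the whole span, degC
    intensity_flagged: float = np.nan  # mean exceedance over flagged months only
    season: str = ""
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def flag_hot_months(tmean: np.ndarray, thresholds: MonthlyClimatology) -> np.ndarray:
    """flag[t] = tmean[t] > threshold[calendar month of t] (strict)."""
    arr = np.asarray(tmean, dtype=float)
    if thresholds.threshold is None:
        raise ValueError("climatology has no threshold; use percentile_thresholds")
    thr = np.asarray(thresholds.threshold, dtype=float)
    return arr > thr[np.arange(arr.shape[0]) % 12]


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.asarray(flags, dtype=bool))
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def build_events(flags: np.ndarray, gap_concat: int = 3) -> list[HotEvent]:
    """Maximal hot runs, then concatenate spans separated by < gap_concat months."""
    spans = _runs(flags)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 < gap_concat:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    flags = np.asarray(flags, dtype=bool)
    for s, e in merged:
        out.append(HotEvent(start=s, end=e, flagged=flags[s : e + 1].copy()))
    return out


def characterize_event(
    event: HotEvent,
    tmean: np.ndarray,
    climatology: MonthlyClimatology,
    start_year: int = 2001,
) -> HotEvent:
    """Fill duration-derived fields: span-mean intensity, flagged-only
    intensity, season of the start month (December starts count as DJF)."""
    arr = np.asarray(tmean, dtype=float)
    if event.start < 0 or event.end >= arr.shape[0]:
        raise ValueError(f"event span [{event.start}, {event.end}] outside record")
    span = np.arange(event.start, event.end + 1)
    exceed = arr[span] - climatology.mean[span % 12]
    event.intensity = float(exceed.mean())
    if event.flagged.size == event.duration and event.flagged.any():
        event.intensity_flagged = float(exceed[event.flagged].mean())
    else:
        event.intensity_flagged = event.intensity
    event.season = SEASON_OF_MONTH[event.start % 12 + 1]
    return event


def detect_hot_events(
    tmean: np.ndarray,
    years: int,
    q: float = 0.90,
    gap_concat: int = 3,
    city_id: str = "",
    dataset_id: str = "",
) -> tuple[list[HotEvent], MonthlyClimatology]:
    """Thresholds -> flags -> merged/concatenated, characterized events."""
    clim = percentile_thresholds(tmean, years, q=q)
    flags = flag_hot_months(tmean, clim)
    events = build_events(flags, gap_concat=gap_concat)
    for ev in events:
        characterize_event(ev, tmean, clim)
        ev.city_id = city_id
        ev.dataset_id = dataset_id
    return events, clim


def stratify_events(events: list[HotEvent]) -> list[str]:
    """Label events long/intense with inclusive thresholds (4 months, 2 degC)."""
    labels = []
    for ev in events:
        long_ = ev.duration >= DURATION_STRATUM_MONTHS
        intense = ev.intensity >= INTENSITY_STRATUM_DEGC
        if long_ and intense:
            labels.append("long_and_intense")
        elif long_:
            labels.append("long_only")
        elif intense:
            labels.append("intense_only")
        else:
            labels.append("neither")
    return labels


def events_frame(events: list[HotEvent], start_year: int = 2001) -> pd.DataFrame:
    strata = stratify_events(events)
    rows = []
    for ev, st in zip(events, strata):
        rows.append(
            {
                "city": ev.city_id,
                "dataset": ev.dataset_id,
                "start": f"{start_year + ev.start // 12:04d}-{ev.start % 12 + 1:02d}",
                "end": f"{start_year + ev.end // 12:04d}-{ev.end % 12 + 1:02d}",
                "start_index": ev.start,
                "end_index": ev.end,
                "duration": ev.duration,
                "intensity": ev.intensity,
                "season": ev.season,
                "stratum": st,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "city", "dataset", "start", "end", "start_index", "end_index",
            "duration", "intensity", "season", "stratum",
        ],
    )
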