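"""Urban-vs-rural comparison statistics: sign fractions, magnitude medians,
urban-minus-rural deltas and their significance.

Signs and magnitudes are compared separately: a lower urban median could
reflect either fewer positive pixels or uniformly smaller magnitudes, so
each (city, season, metric, area) pool reports the fraction of positive
pixels (exact zeros excluded), the median absolute value over all pixels
and over positive-only / negative-only pixels, and the median raw value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("resistance", "recovery")
PERCENTILES = (5, 25, 50, 75, 95)

_STAT_NAMES = ("frac_pos", "median_abs", "median_abs_pos", "median_abs_neg", "median_raw")


def significance_median(values) -> float:
    """Two-sided Wilcoxon signed-rank test of median = 0.

    Exact null for n <= 25, normal approximation above; all-zero input
    returns p = 1 by convention (no evidence of departure).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan
    nz = x[x != 0.0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    return float(stats.wilcoxon(nz, alternative="two-sided", method=method).pvalue)


def _pool_stats(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    out = {name: np.nan for name in _STAT_NAMES}
    out["n"] = int(v.size)
    out["p_median"] = np.nan
    if v.size == 0:
        return out
    nz = v[v != 0.0]
    out["frac_pos"] = float((nz > 0).mean()) if nz.size else np.nan
    out["median_abs"] = float(np.median(np.abs(v)))
    pos, neg = v[v > 0], v[v < 0]
    out["median_abs_pos"] = float(np.median(pos)) if pos.size else np.nan
    out["median_abs_neg"] = float(np.median(np.abs(neg))) if neg.size else np.nan
    out["median_raw"] = float(np.median(v))
    out["p_median"] = significance_median(v)
    return out


def city_season_summary(records: pd.DataFrame, region: dict[str, str] | None = None) -> pd.DataFrame:
    """Per (city, season, metric) urban and rural pooled statistics + deltas.

    Pools valid records over pixels, events and datasets.  Empty pools are
    emitted as missing with n = 0.
    """
    rows = []
    for (city, season), grp in records.groupby(["city", "season"], sort=True):
        for metric in METRICS:
            valid = grp[grp[f"valid_{metric}"].astype(bool)]
            row = {"city": city, "season": season, "metric": metric}
            if region is not None:
                row["region"] = region.get(city, "")
            for area in ("urban", "rural"):
                st = _pool_stats(valid.loc[valid["area"] == area, metric].to_numpy())
                row.update({f"{area}_{k}": v for k, v in st.items()})
            for name in _STAT_NAMES:
                row[f"delta_{name}"] = row[f"urban_{name}"] - row[f"rural_{name}"]
            rows.append(row)
    return pd.DataFrame(rows)


def event_level_deltas(records: pd.DataFrame) -> pd.DataFrame:
    """Per (city, dataset, event, metric) urban-minus-rural deltas.

    The unit of pooling for distribution plots and the driver screens: one
    row per hot event per metric per ensemble member.
    """
    rows = []
    keys = ["city", "dataset", "event", "season"]
    for key_vals, grp in records.groupby(keys, sort=True):
        for metric in METRICS:
            valid = grp[grp[f"valid_{metric}"].astype(bool)]
            urb = _pool_stats(valid.loc[valid["area"] == "urban", metric].to_numpy())
            rur = _pool_stats(valid.loc[valid["area"] == "rural", metric].to_numpy())
            row = dict(zip(keys, key_vals))
            row["metric"] = metric
            row["duration"] = grp["duration"].iloc[0]
            row["intensity"] = grp["intensity"].iloc[0]
            row["n_urban"] = urb["n"]
            row["n_rural"] = rur["n"]
            for name in _STAT_NAMES:
                row[f"delta_{name}"] = urb[name] - rur[name]
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_distribution(deltas) -> dict:
    """Percentile summary (5/25/50/75/95, linear interpolation) plus the
    significance of the median."""
    x = np.asarray(deltas, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no deltas to aggregate")
    pct = np.percentile(x, PERCENTILES, method="linear")
    out = {f"p{p}": float(v) for p, v in zip(PERCENTILES, pct)}
    out["median"] = out["p50"]
    out["p_median"] = significance_median(x)
    out["n"] = int(x.size)
    return out


def regional_split(stats: pd.DataFrame, region: dict[str, str]) -> pd.DataFrame:
    """Group per-city stats (or deltas) into regions (e.g. east/west) and
    summarize each delta column's distribution per (region, season, metric)."""
    df = stats.copy()
    df["region"] = df["city"].map(region).fillna("")
    delta_cols = [c for c in df.columns if c.startswith("delta_")]
    rows = []
    for (reg, season, metric), grp in df.groupby(["region", "season", "metric"], sort=True):
        row = {"region": reg, "season": season, "metric": metric, "n": len(grp)}
        for col in delta_cols:
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"{col}_median"] = float(np.median(vals)) if vals.size else np.nan
            row[f"{col}_p"] = significance_median(vals) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def seasonal_report(deltas: pd.DataFrame) -> str:
    """Plain-text panel report: 4 seasons x delta statistics x 2 metrics."""
    lines = []
    for metric in METRICS:
        lines.append(f"== {metric} ==")
        sub = deltas[deltas["metric"] == metric]
        for name in _STAT_NAMES:
            col = f"delta_{name}"
            lines.append(f"  urban - rural {name}:")
            for season in ("DJF", "MAM", "JJA", "SON"):
                vals = sub.loc[sub["season"] == season, col].dropna().to_numpy()
                if vals.size == 0:
                    lines.append(f"    {season}: (no events)")
                    continue
                agg = aggregate_distribution(vals)
                sig = "*" if agg["p_median"] <= 0.05 else " "
                lines.append(
                    f"    {season}: median {agg['median']:+.4f}{sig} "
                    f"[p5 {agg['p5']:+.4f}, p95 {agg['p95']:+.4f}] n={agg['n']}"
                )
    return "\n".join(lines)
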