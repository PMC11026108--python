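"""Pixel-scale attribution of urban-rural response differences within
land-cover groups: random-forest sign classification / magnitude
regression, exact path (Saabas) contributions against a rural baseline,
contribution significance, and partial dependence.

Each tree routes a sample from root to leaf; every split changes the
running mean prediction, and that change is attributed to the split
feature.  Summing over the path gives an exact additive decomposition
prediction = bias + sum_f contribution_f.  The reported contribution of a
feature for a row is its path attribution minus that of the group's
rural-centroid feature vector, so positive values read as "pushed the
urban prediction above the rural baseline".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .scene import LAND_COVER_TYPES

logger = logging.getLogger(__name__)

MIN_GROUP_ROWS = 200
N_TREES = 500
PIXEL_PREDICTORS = [
    "corr_spi", "corr_vpd", "optimal_tmax", "optimal_tmin",
    "dtmax_in_post_event", "dtmin_in_post_event", "impervious_frac", "elev",
    "dominant_lc_frac",
]


def build_groups(city_land_cover: pd.DataFrame) -> dict[str, list[str]]:
    """Group cities by dominant rural land-cover type.

    city_land_cover: one row per city with the 7 rural fraction columns.
    Crop-dominant cities are excluded; ties break to the earliest type in
    the canonical order (and are logged).
    """
    groups: dict[str, list[str]] = {}
    lc_cols = [c for c in LAND_COVER_TYPES if c in city_land_cover.columns]
    for _, row in city_land_cover.iterrows():
        fracs = np.array([row[c] for c in lc_cols], dtype=float)
        best = float(fracs.max())
        winners = [lc_cols[i] for i in range(len(lc_cols)) if fracs[i] == best]
        if len(winners) > 1:
            logger.info("city %s: dominant land-cover tie %s, taking %s",
                        row["city"], winners, winners[0])
        dominant = winners[0]
        if dominant == "Crop":
            continue
        groups.setdefault(dominant, []).append(row["city"])
    return groups


def fit_rf(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    seed: int = 0,
    n_estimators: int = N_TREES,
    min_rows: int = MIN_GROUP_ROWS,
):
    """Random forest with fixed, documented hyperparameters.

    task 'sign' -> classifier on a binary target (sqrt-p features per
    split); task 'magnitude' -> regressor (p/3 features per split).
    Returns (fitted forest, out-of-bag score).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < min_rows:
        raise ValueError(f"need >= {min_rows} rows, got {X.shape[0]}")
    if task == "sign":
        if np.unique(y).size < 2:
            raise ValueError("sign classification needs both classes present")
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            oob_score=True, random_state=seed, n_jobs=1,
        )
    elif task == "magnitude":
        forest = RandomForestRegressor(
            n_estimators=n_estimators, max_features=1.0 / 3.0,
            oob_score=True, random_state=seed, n_jobs=1,
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    forest.fit(X, y)
    return forest, float(forest.oob_score_)


def _tree_value(tree, is_classifier: bool) -> np.ndarray:
    v = tree.tree_.value
    if is_classifier:
        probs = v[:, 0, :]
        probs = probs / probs.sum(axis=1, keepdims=True)
        return probs[:, 1]  # probability of the positive class
    return v[:, 0, 0]


def saabas_decomposition(forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact path attribution: returns (bias (n,), contributions (n, p))
    with prediction = bias + contributions.sum(axis=1) per row."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    is_clf = isinstance(forest, RandomForestClassifier)
    contrib = np.zeros((n, p))
    bias = 0.0
    for est in forest.estimators_:
        t = est.tree_
        val = _tree_value(est, is_clf)
        parent = np.full(t.node_count, -1, dtype=int)
        for node in range(t.node_count):
            for child in (t.children_left[node], t.children_right[node]):
                if child != -1:
                    parent[child] = node
        delta = np.zeros(t.node_count)
        attr = np.full(t.node_count, -1, dtype=int)
        nonroot = parent >= 0
        delta[nonroot] = val[nonroot] - val[parent[nonroot]]
        attr[nonroot] = t.feature[parent[nonroot]]
        D = np.zeros((t.node_count, p))
        D[np.flatnonzero(nonroot), attr[nonroot]] = delta[nonroot]
        path = est.decision_path(X)
        contrib += path @ D
        bias += val[0]
    k = len(forest.estimators_)
    return np.full(n, bias / k), contrib / k


def predict_target(forest, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if isinstance(forest, RandomForestClassifier):
        return forest.predict_proba(X)[:, 1]
    return forest.predict(X)


def contributions(forest, X: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Per-row, per-feature contributions to prediction(row) - prediction(baseline).

    baseline is a single feature vector (the group's rural centroid); the
    bias terms cancel, so per-row additivity is exact:
    contributions.sum(axis=1) == predict(row) - predict(baseline).
    """
    X = np.asarray(X, dtype=float)
    base = np.asarray(baseline, dtype=float).reshape(1, -1)
    _, c_rows = saabas_decomposition(forest, X)
    _, c_base = saabas_decomposition(forest, base)
    return c_rows - c_base


def contribution_significance(
    predictor_values, per_row_contributions, min_n: int = 8
) -> tuple[bool, float]:
    """Spearman correlation between a predictor and its per-row contribution;
    significant when p <= 0.05.  Constant contributions are never significant."""
    x = np.asarray(predictor_values, dtype=float)
    c = np.asarray(per_row_contributions, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(c))
    x, c = x[ok], c[ok]
    if x.size < min_n or np.ptp(c) == 0 or np.ptp(x) == 0:
        return False, np.nan
    res = stats.spearmanr(x, c)
    return bool(res.pvalue <= 0.05), float(res.pvalue)


def partial_dependence(forest, X: np.ndarray, feature: int, grid: int = 20) -> pd.DataFrame:
    """Mean prediction as one feature sweeps a grid over its observed range
    (5th-95th percentile, avoiding leaf artifacts at the exact extremes),
    all other features held at their observed values."""
    X = np.asarray(X, dtype=float)
    lo, hi = np.nanpercentile(X[:, feature], [5.0, 95.0])
    values = np.linspace(lo, hi, grid) if grid > 1 else np.array([(lo + hi) / 2.0])
    preds = []
    for v in values:
        Xv = X.copy()
        Xv[:, feature] = v
        preds.append(float(predict_target(forest, Xv).mean()))
    return pd.DataFrame({"value": values, "prediction": preds})


def contribution_table(
    forest,
    X: np.ndarray,
    feature_names: list[str],
    baseline: np.ndarray,
) -> pd.DataFrame:
    """Summary per predictor: mean signed contribution (vs the rural
    baseline), rank by |mean contribution| (1 = largest), and the Spearman
    significance flag."""
    contrib = contributions(forest, X, baseline)
    mean_c = contrib.mean(axis=0)
    order = np.argsort(-np.abs(mean_c), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    rows = []
    X = np.asarray(X, dtype=float)
    for j, name in enumerate(feature_names):
        sig, p = contribution_significance(X[:, j], contrib[:, j])
        rows.append({"predictor": name, "mean_contribution": float(mean_c[j]),
                     "rank": int(rank[j]), "significant": sig, "p": p})
    return pd.DataFrame(rows).sort_values("rank", ignore_index=True)


def prepare_group_matrix(
    pixel_table: pd.DataFrame,
    group_cities: list[str],
    dominant_lc: str,
    metric: str,
    target: str,
    predictors: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, baseline, names) for one land-cover group.

    Rows are urban pixel-events of the member cities with a valid metric;
    the sign target is binary (positive = 1, exact zeros dropped); the
    magnitude target is |metric|.  The baseline vector is the rural-pixel
    centroid when rural rows are present, else the group centroid.
    Missing predictor values are median-imputed.
    """
    names = list(predictors) if predictors is not None else list(PIXEL_PREDICTORS)
    df = pixel_table[pixel_table["city"].isin(group_cities)].copy()
    df = df[df[f"valid_{metric}"].astype(bool)]
    df["dominant_lc_frac"] = df[dominant_lc] if dominant_lc in df.columns else 0.0
    if target == "sign":
        df = df[df[metric] != 0.0]
        y = (df[metric] > 0).to_numpy(dtype=int)
    elif target == "magnitude":
        y = df[metric].abs().to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown target {target!r}")
    rural = df[df["area"] == "rural"] if "area" in df.columns else df.iloc[0:0]
    base_src = rural if len(rural) else df
    X = df[names].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(med, idx[1])
    baseline = np.nanmean(base_src[names].to_numpy(dtype=float), axis=0)
    baseline = np.where(np.isnan(baseline), med, baseline)
    urban_rows = (df["area"] == "urban").to_numpy() if "area" in df.columns else np.ones(len(df), bool)
    return X[urban_rows], y[urban_rows], baseline, names
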