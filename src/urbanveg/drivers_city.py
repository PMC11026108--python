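"""City-scale driver screening: Spearman / partial Spearman correlations and
single- or multi-predictor GAMs relating predictors to urban-rural
response differences.

Land-cover fractions are compositional (they sum to at most one), so
their marginal rank correlations are confounded by the other types; the
screen therefore partials the other land-cover fractions out of both the
predictor and the response before correlating.  GAMs use penalized
B-spline smooths; models are compared by in-sample R^2 and an AIC of the
fixed convention n*log(RSS/n) + 2*edf (constant terms dropped), which is
comparable across models on the same response.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .scene import LAND_COVER_TYPES

logger = logging.getLogger(__name__)

MIN_SPEARMAN_ROWS = 8
GAM_DF = 6  # df=5 cubic B-splines cannot represent a full oscillation
GAM_ALPHA = 0.1


def spearman_screen(x, y, min_n: int = MIN_SPEARMAN_ROWS) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (average ranks on ties).

    Returns (nan, nan) for too few complete pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def partial_spearman_screen(
    x, y, covariates: np.ndarray, min_extra_rows: int = 5
) -> tuple[float, float]:
    """Partial Spearman: Pearson correlation of the residuals of the ranked
    predictor and response after OLS on the ranked covariates.

    Collinear or constant covariate columns are dropped with a warning.
    p-value from the t distribution with n - 2 - k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != x.shape[0]:
        Z = Z.T
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    x, y, Z = x[ok], y[ok], Z[ok]
    # drop constant columns, then any column not raising matrix rank
    keep = [j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
    if len(keep) < Z.shape[1]:
        logger.warning("dropping %d constant covariate(s)", Z.shape[1] - len(keep))
    Z = Z[:, keep]
    if Z.shape[1]:
        q, r = np.linalg.qr(Z - Z.mean(axis=0))
        indep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        if not indep.all():
            logger.warning("dropping %d collinear covariate(s)", int((~indep).sum()))
            Z = Z[:, indep]
    k = Z.shape[1]
    n = x.size
    if n < k + 5 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx, ry = _rank(x), _rank(y)
    if k == 0:
        return spearman_screen(x, y, min_n=min(n, MIN_SPEARMAN_ROWS))
    rz = _rank(Z)
    design = np.column_stack([np.ones(n), rz])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    if np.ptp(ex) == 0 or np.ptp(ey) == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    if df < 1 or abs(rho) >= 1.0:
        return rho, np.nan
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def gam_screen(
    X, y, df_basis: int = GAM_DF, alpha: float = GAM_ALPHA
) -> tuple[float, float]:
    """Penalized-spline additive model of y on the columns of X.

    Returns (R^2, AIC).  R^2 is in-sample, clipped to [0, 1]; AIC uses the
    documented convention n*log(RSS/n) + 2*edf with edf the total
    effective degrees of freedom (including intercept).  A constant
    response yields R^2 = 0 by convention.  Non-convergence returns NaNs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    X, y = X[ok], y[ok]
    n, p = X.shape
    if np.ptp(y) == 0:
        return 0.0, np.nan
    if n < 3 * df_basis:
        return np.nan, np.nan
    try:
        bs = BSplines(X, df=[df_basis] * p, degree=[3] * p)
        res = GLMGam(y, smoother=bs, alpha=[alpha] * p).fit()
        resid = np.asarray(res.resid_response)
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = max(0.0, min(1.0, 1.0 - rss / tss)) if tss > 0 else 0.0
        edf = float(np.sum(res.edf)) + 1.0  # smooth terms + intercept
        aic = n * np.log(max(rss, 1e-300) / n) + 2.0 * edf
        return r2, float(aic)
    except Exception as exc:  # pragma: no cover - convergence failures
        logger.warning("GAM failed: %s", exc)
        return np.nan, np.nan


def screen_drivers(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    land_cover: tuple[str, ...] = LAND_COVER_TYPES,
    season: str | None = None,
) -> pd.DataFrame:
    """Full per-season screen: Spearman for non-land-cover predictors,
    partial Spearman for land-cover fractions (partialling out the other
    types), univariate GAMs per predictor and one 7-smooth land-cover GAM.

    Long-format result: season, response, predictor, rho, p, gam_r2, gam_aic.
    """
    df = table if season is None else table[table["season"] == season]
    lc_present = [c for c in land_cover if c in df.columns]
    rows = []
    y = df[response].to_numpy(dtype=float)
    for pred in predictors:
        x = df[pred].to_numpy(dtype=float)
        rho, p = spearman_screen(x, y)
        r2, aic = gam_screen(x[:, None], y)
        rows.append({"season": season or "all", "response": response, "predictor": pred,
                     "kind": "spearman", "rho": rho, "p": p, "gam_r2": r2, "gam_aic": aic})
    for lc in lc_present:
        others = [c for c in lc_present if c != lc]
        rho, p = partial_spearman_screen(
            df[lc].to_numpy(dtype=float), y, df[others].to_numpy(dtype=float)
        )
        rows.append({"season": season or "all", "response": response, "predictor": lc,
                     "kind": "partial_spearman", "rho": rho, "p": p,
                     "gam_r2": np.nan, "gam_aic": np.nan})
    if lc_present:
        r2, aic = gam_screen(df[lc_present].to_numpy(dtype=float), y)
        rows.append({"season": season or "all", "response": response, "predictor": "Land Cover",
                     "kind": "gam_multi", "rho": np.nan, "p": np.nan,
                     "gam_r2": r2, "gam_aic": aic})
    return pd.DataFrame(rows)
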