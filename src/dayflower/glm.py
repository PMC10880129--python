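"""Gaussian-identity GLM comparisons and AIC-based landscape-scale selection.

A Gaussian GLM with identity link is ordinary least squares; fits are
delegated to statsmodels OLS.  AIC is computed as -2*logLik + 2*(k + 1)
where k counts the mean parameters (intercept + slopes) and the +1 is the
error-variance parameter, with the Gaussian log-likelihood including its
normalising constants — the convention of R's ``AIC(lm(...))``, so values
are directly comparable with mainstream statistical software.

Habitat comparisons use treatment coding with RA (rural agricultural) as
the reference level.  For scale selection, each diversity metric is
regressed on the developed/agricultural/forest areas at each buffer radius
(250/500/1000 m, z-scored) plus an intercept-only null model; the lowest
AIC wins, ties broken toward fewer predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import HABITATS, RADII, PopulationMeta

GLM_LANDCOVER_CLASSES: tuple[str, ...] = ("developed", "agricultural", "forest")


@dataclass
class GlmFit:
    """A fitted Gaussian/identity GLM (ordinary least squares)."""

    response: str
    predictors: list[str]            # excludes the intercept
    coefficients: pd.Series          # includes "Intercept"
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    rss: float
    n: int
    k: int                           # number of mean parameters (incl. intercept)
    log_likelihood: float
    aic: float


def _fit_ols(y: np.ndarray, X: pd.DataFrame, response: str) -> GlmFit:
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n = {n} <= k = {k}: model not estimable")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    # Gaussian logLik with the ML variance estimate (RSS/n), constants included
    llf = float(res.llf)
    aic = -2.0 * llf + 2.0 * (k + 1)
    return GlmFit(
        response=response,
        predictors=[c for c in X.columns if c != "Intercept"],
        coefficients=res.params,
        std_errors=res.bse,
        t_values=res.tvalues,
        p_values=res.pvalues,
        rss=rss,
        n=n,
        k=k,
        log_likelihood=llf,
        aic=aic,
    )


def fit_gaussian_glm(
    y: Sequence[float],
    X: pd.DataFrame | None = None,
    *,
    habitat: Sequence[str] | None = None,
    response: str = "y",
) -> GlmFit:
    """Fit a Gaussian/identity GLM of y on X, or on habitat dummies.

    Exactly one of `X` / `habitat` must be given.  With `habitat`, the
    design is treatment-coded with RA as the reference, so coefficients are
    urban-habitat contrasts against the rural baseline.
    """
    y = np.asarray(y, dtype=float)
    if (X is None) == (habitat is None):
        raise ValueError("provide exactly one of X or habitat")
    if habitat is not None:
        hab = pd.Categorical(list(habitat), categories=HABITATS)
        if hab.isna().any():
            raise ValueError("unknown habitat code in design")
        X = pd.get_dummies(pd.Series(hab), drop_first=True, dtype=float)
        X.columns = [f"habitat[{c}]" for c in X.columns]
    X = X.copy()
    X.insert(0, "Intercept", 1.0)
    return _fit_ols(y, X, response)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def landscape_design(
    meta: Mapping[str, PopulationMeta],
    pops: Sequence[str],
    radius: int,
    classes: Sequence[str] = GLM_LANDCOVER_CLASSES,
    *,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-population land-cover predictor matrix at one radius (z-scored)."""
    cols = {}
    for cls in classes:
        v = np.array([meta[p].landcover[radius][cls] for p in pops])
        cols[f"{cls}_{radius}"] = _zscore(v) if standardize else v
    return pd.DataFrame(cols, index=list(pops))


@dataclass
class ScaleSelection:
    """AIC grid over {null, 250, 500, 1000} for one response metric."""

    metric: str
    aic: dict[str, float]            # keys "null", "250", "500", "1000"
    best: str                        # argmin key, ties -> fewer predictors
    null_wins: bool
    fits: dict[str, GlmFit]


def select_landscape_scale(
    metrics: pd.DataFrame,
    meta: Mapping[str, PopulationMeta],
    *,
    classes: Sequence[str] = GLM_LANDCOVER_CLASSES,
    radii: Sequence[int] = RADII,
) -> dict[str, ScaleSelection]:
    """For each metric column, compare the null model against one model per radius.

    Candidate models share the response; predictors are the selected
    land-cover areas at a single radius.  The null (intercept-only) model
    is listed first so that exact AIC ties resolve toward fewer predictors.
    """
    pops = list(metrics.index)
    for p in pops:
        for rad in radii:
            if rad not in meta[p].landcover:
                raise ValueError(f"population {p} lacks land cover at {rad} m")
    out: dict[str, ScaleSelection] = {}
    for metric in metrics.columns:
        y = metrics[metric].to_numpy(dtype=float)
        fits: dict[str, GlmFit] = {}
        null_X = pd.DataFrame(index=pops)
        fits["null"] = fit_gaussian_glm(y, null_X, response=metric)
        for rad in radii:
            X = landscape_design(meta, pops, rad, classes)
            fits[str(rad)] = fit_gaussian_glm(y, X, response=metric)
        aics = {name: f.aic for name, f in fits.items()}
        best = min(aics, key=lambda name: (round(aics[name], 9), fits[name].k))
        out[metric] = ScaleSelection(metric, aics, best, best == "null", fits)
    return out


def selection_report(selections: Mapping[str, ScaleSelection]) -> pd.DataFrame:
    """Tidy metric x {null, 250, 500, 1000} AIC grid with the winning scale."""
    rows = []
    for metric, sel in selections.items():
        row: dict[str, object] = {"metric": metric}
        row.update({f"AIC_{k}": v for k, v in sel.aic.items()})
        row["best"] = sel.best
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
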