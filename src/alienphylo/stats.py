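"""Comparative statistics over NRI/NTI tables: data-mode selection by AICc,
two-way ANOVA with Holm-adjusted post hocs, climate regressions, and
Spearman correlations between community types.

Model fitting is delegated to statsmodels; this module fixes the
conventions that make results reproducible: Gaussian family by default
(the response, an SES, is unbounded), AIC recomputed from the
log-likelihood with k = coefficients + 1 so the residual-variance parameter
is counted, AICc = AIC + 2k(k+1)/(n−k−1), Type-II sums of squares for the
(possibly unbalanced) two-way ANOVA, Welch t for pairwise comparisons, and
Holm step-down adjustment of p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "CorrelationResult",
    "aggregate_climate",
    "glm_fit",
    "aicc",
    "select_data_mode",
    "two_way_anova",
    "holm_adjust",
    "posthoc_pairwise",
    "spearman",
    "climate_regressions",
]


@dataclass
class ModelFit:
    """One fitted regression with the information criteria used for model
    choice."""

    response: str
    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    aicc: float
    n: int
    k: int  # estimated parameters incl. intercept and residual variance
    result: object = field(repr=False, default=None)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    metric: str
    scale: str
    rho: float
    p: float
    n: int


def aicc(aic: float, n: int, k: int) -> float:
    """Small-sample corrected AIC; NaN (undefined) when n ≤ k + 1."""
    if n <= k + 1:
        return float("nan")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aggregate_climate(grid: pd.DataFrame, partitions: dict) -> pd.DataFrame:
    """Per-unit means of the climate surface at each spatial scale.

    A unit's value is the unweighted mean over grid cells whose centers fall
    inside it; units containing no cell center get NaN (flagged missing).
    """
    from shapely import STRtree
    from shapely.geometry import Point

    pts = np.array(
        [Point(x, y) for x, y in zip(grid["lon"], grid["lat"])], dtype=object
    )
    rows = []
    for scale, units in partitions.items():
        units = sorted(units, key=lambda u: u[0])
        tree = STRtree([p for _, p in units])
        pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
        assign = {}
        for p, u in zip(pt_idx, poly_idx):
            if p not in assign or u < assign[p]:
                assign[p] = u
        by_unit: dict[int, list[int]] = {}
        for p, u in assign.items():
            by_unit.setdefault(u, []).append(p)
        for i, (unit_id, _) in enumerate(units):
            cells = by_unit.get(i, [])
            if not cells:
                logger.warning("unit %s contains no grid-cell centers", unit_id)
            rows.append(
                {
                    "scale": scale,
                    "unit": unit_id,
                    "bio1": grid["bio1"].iloc[cells].mean() if cells else np.nan,
                    "bio12": grid["bio12"].iloc[cells].mean() if cells else np.nan,
                }
            )
    return pd.DataFrame(rows)


def glm_fit(
    table: pd.DataFrame,
    response: str,
    predictors,
    family: str = "gaussian",
) -> ModelFit:
    """Fit response ~ predictors and report coefficients, AIC and AICc."""
    predictors = list(predictors)
    cols = [response] + predictors
    data = table[cols].dropna()
    y = data[response].to_numpy(dtype=float)
    X = sm.add_constant(data[predictors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
    elif family == "binomial":
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    names = ["Intercept"] + predictors
    n = len(data)
    k = X.shape[1] + (1 if family == "gaussian" else 0)
    aic = -2.0 * res.llf + 2.0 * k
    return ModelFit(
        response=response,
        predictors=predictors,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        llf=float(res.llf),
        aic=float(aic),
        aicc=aicc(float(aic), n, k),
        n=n,
        k=k,
        result=res,
    )


def select_data_mode(
    results_by_mode: dict[str, pd.DataFrame],
    metrics=("NRI", "NTI"),
) -> dict:
    """Choose presence vs abundance scoring by summed AICc.

    For each data mode the same model — metric ~ community type + spatial
    scale — is fitted per metric; the mode with the lower summed AICc wins,
    with ties going to abundance (uneven species counts between communities
    make abundance weighting the safer default).
    """
    if set(results_by_mode) != {"presence", "abundance"}:
        raise ValueError("need exactly the 'presence' and 'abundance' tables")
    scores, fits = {}, {}
    for mode, table in results_by_mode.items():
        t = table.dropna(subset=list(metrics)).copy()
        dummies = pd.get_dummies(
            t[["community_type", "scale"]], drop_first=True, dtype=float
        )
        t = pd.concat([t, dummies], axis=1)
        total = 0.0
        fits[mode] = {}
        for metric in metrics:
            fit = glm_fit(t, metric, list(dummies.columns))
            if np.isnan(fit.aicc):
                raise ValueError(f"AICc undefined for mode {mode!r} ({metric})")
            total += fit.aicc
            fits[mode][metric] = fit
        scores[mode] = total
    tie = np.isclose(scores["presence"], scores["abundance"])
    selected = (
        "abundance" if tie or scores["abundance"] < scores["presence"]
        else "presence"
    )
    if tie:
        logger.info("AICc tie between data modes; abundance selected")
    return {
        "selected": selected,
        "tie": bool(tie),
        "aicc": scores,
        "delta_aicc": abs(scores["presence"] - scores["abundance"]),
        "fits": fits,
    }


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str = "community_type",
    factor_b: str = "scale",
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type-II sums of squares.

    Returns a tidy table (term, sum_sq, df1, df2, F, p_raw). Requires at
    least two levels per factor and no empty cells; a constant response is
    flagged (all F set to 0, ``degenerate=True`` attribute on the frame).
    """
    data = table[[response, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    n_cells = data[factor_a].nunique() * data[factor_b].nunique()
    if len(cells) < n_cells:
        raise ValueError("empty factor-combination cell")
    degenerate = data[response].nunique() == 1
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data
    ).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    resid_df = float(tab.loc["Residual", "df"])
    out = []
    names = {0: factor_a, 1: factor_b, 2: f"{factor_a}:{factor_b}"}
    for i, (term, r) in enumerate(tab.drop(index="Residual").iterrows()):
        F = 0.0 if degenerate else float(r["F"])
        out.append(
            {
                "term": names[i],
                "sum_sq": float(r["sum_sq"]),
                "df1": float(r["df"]),
                "df2": resid_df,
                "F": F,
                "p_raw": float("nan") if degenerate else float(r["PR(>F)"]),
            }
        )
    res = pd.DataFrame(out)
    res.attrs["degenerate"] = degenerate
    return res


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sorted ascending, the i-th adjusted value is the running maximum of
    min(1, (m − i + 1)·p_(i)), mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    stepdown = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj = np.maximum.accumulate(stepdown)
    out = np.empty(m)
    out[order] = adj
    return out


def posthoc_pairwise(
    table: pd.DataFrame,
    value: str,
    group: str,
    adjust: str = "holm",
    welch: bool = True,
) -> pd.DataFrame:
    """All pairwise two-sample t comparisons with Holm-adjusted p-values.

    Welch (unequal-variance) t by default; set ``welch=False`` for the
    pooled-variance test.
    """
    if adjust != "holm":
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = {g: sub[value].dropna().to_numpy() for g, sub in table.groupby(group)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with < 2 observations: {small}")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=not welch)
        rows.append(
            {
                "group_a": a, "group_b": b, "statistic": float(t),
                "n_a": len(groups[a]), "n_b": len(groups[b]),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    out["method"] = ("welch_t" if welch else "pooled_t") + "+holm"
    return out


def spearman(x, y, metric: str = "", scale: str = "",
             pair: tuple[str, str] = ("", "")) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(
        pair=pair, metric=metric, scale=scale,
        rho=float(rho), p=float(p), n=int(x.size),
    )


def climate_regressions(
    results: pd.DataFrame,
    covariates: pd.DataFrame,
    metrics=("NRI", "NTI"),
    climate_vars=("bio1", "bio12"),
) -> pd.DataFrame:
    """Per-stratum regressions of each metric on each climate variable.

    Strata are community_type × scale; within each, metric ~ BIO1 and
    metric ~ BIO12 are fitted separately. Strata too small for AICc
    (n ≤ k + 1) or with a constant covariate are skipped with a log entry.
    Returns a tidy table (scale, community_type, metric, climate_var, slope,
    se, p_raw, AIC, AICc, n).
    """
    joined = results.merge(covariates, on=["scale", "unit"], how="inner")
    rows = []
    for (ctype, scale), grp in joined.groupby(["community_type", "scale"]):
        for metric in metrics:
            for var in climate_vars:
                sub = grp.dropna(subset=[metric, var])
                if len(sub) <= 3:  # n <= k+1 with k = 3 (intercept+slope+var)
                    logger.info(
                        "skipping %s/%s %s~%s: n=%d too small",
                        ctype, scale, metric, var, len(sub),
                    )
                    continue
                if sub[var].nunique() < 2:
                    logger.info(
                        "skipping %s/%s %s~%s: constant covariate",
                        ctype, scale, metric, var,
                    )
                    continue
                fit = glm_fit(sub, metric, [var])
                rows.append(
                    {
                        "scale": scale, "community_type": ctype,
                        "metric": metric, "climate_var": var,
                        "slope": float(fit.params[var]),
                        "se": float(fit.bse[var]),
                        "p_raw": float(fit.pvalues[var]),
                        "AIC": fit.aic, "AICc": fit.aicc, "n": fit.n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["scale", "community_type", "metric", "climate_var",
                 "slope", "se", "p_raw", "AIC", "AICc", "n"],
    )


def community_type_correlations(
    results: pd.DataFrame,
    metrics=("NRI", "NTI"),
    community_types=("Inv", "Nat", "Int", "InvNat", "InvInt", "NatInt"),
) -> pd.DataFrame:
    """Spearman correlations of per-unit metrics between community types.

    Within each spatial scale and metric, every pair of community types is
    correlated across the units where both are defined; pairs with fewer
    than three shared units are skipped.
    """
    rows = []
    for scale, grp in results.groupby("scale"):
        wide = {
            metric: grp.pivot_table(
                index="unit", columns="community_type", values=metric
            )
            for metric in metrics
        }
        for metric in metrics:
            w = wide[metric]
            for a, b in combinations(
                [c for c in community_types if c in w.columns], 2
            ):
                sub = w[[a, b]].dropna()
                if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                    continue
                r = spearman(sub[a], sub[b], metric=metric, scale=scale,
                             pair=(a, b))
                rows.append(
                    {
                        "scale": scale, "metric": metric,
                        "type_a": a, "type_b": b,
                        "rho": r.rho, "p_raw": r.p, "n": r.n,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["scale", "metric", "type_a", "type_b", "rho", "p_raw", "n"]
    )
    if len(out):
        out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = []
    return out
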