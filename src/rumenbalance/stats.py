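"""Statistical stages of the balance analysis.

Covers the standardization + isometry test of the protein vs digestible-
energy relationship, the balance-ratio vs fiber regression (optionally with
a diet-type interaction and a quasi-binomial cross-check), Pearson
correlation matrices, one-way ANOVA with Tukey HSD pairwise comparisons,
and the subpopulation-level body-mass regression.

Conventions: all tests are two-sided at alpha = 0.05; ordinary least squares
throughout (not major-axis regression); on standardized inputs the OLS slope
equals the Pearson correlation, which several tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegressionResult",
    "InteractionModel",
    "AnovaResult",
    "standardize",
    "isometry_test",
    "ratio_fiber_model",
    "quasibinomial_ratio_model",
    "pearson_matrix",
    "anova_tukey",
    "subpop_ratio_vs_bodymass",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple-OLS summary with tests of the slope against 0 and against 1."""

    slope: float
    intercept: float
    slope_se: float
    t_vs_zero: float
    p_vs_zero: float
    t_vs_one: float
    p_vs_one: float
    r_squared: float
    df: int
    n: int

    @property
    def p_two_sided(self) -> float:
        """Two-sided p of the slope against zero (the default null)."""
        return self.p_vs_zero


@dataclass(frozen=True)
class InteractionModel:
    """Full-interaction linear model of a response on x across groups.

    Reference-level parameterization: ``slopes``/``intercepts`` give the
    per-group fitted lines; ``contrasts`` holds the interaction terms
    (difference in slope vs the reference group) with t and p.
    """

    reference: str
    slopes: dict[str, float]
    intercepts: dict[str, float]
    contrasts: pd.DataFrame  # term, estimate, se, t, p
    df_resid: int
    r_squared: float
    interaction_p: float  # joint F-test of all interaction terms


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def standardize(values) -> np.ndarray:
    """z-scores: subtract the mean, divide by the sample SD (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize needs a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance, cannot standardize")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    n = len(y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se == 0.0 or 1.0 - fit.rsquared < 1e-14:
        # numerically perfect fit: the slope is exact, t-statistics are
        # degenerate (0 when the null matches the slope, +-inf otherwise)
        slope = 1.0 if abs(slope - 1.0) < 1e-9 else slope
        se = 0.0
        t0 = np.inf if slope != 0 else 0.0
        t1 = 0.0 if slope == 1.0 else np.copysign(np.inf, slope - 1.0)
        p0 = 0.0 if slope != 0 else 1.0
        p1 = 1.0 if slope == 1.0 else 0.0
    else:
        t0 = slope / se
        t1 = (slope - 1.0) / se
        p0 = 2.0 * sps.t.sf(abs(t0), n - 2)
        p1 = 2.0 * sps.t.sf(abs(t1), n - 2)
    return RegressionResult(
        slope=slope, intercept=float(fit.params[0]), slope_se=se,
        t_vs_zero=float(t0), p_vs_zero=float(p0),
        t_vs_one=float(t1), p_vs_one=float(p1),
        r_squared=float(fit.rsquared), df=n - 2, n=n,
    )


def isometry_test(y, x) -> RegressionResult:
    """OLS of y on x with a two-sided test of slope = 1 (isometric scaling).

    Intended for standardized inputs, where the fitted slope equals the
    Pearson correlation and a slope of 1 means the two components scale
    proportionally (1:1).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {x.shape}")
    if len(y) < 3:
        raise ValueError("isometry test needs n >= 3")
    return _ols(y, x)


def ratio_fiber_model(ratio, fiber_pct, diet_type=None, *,
                      standardized: bool | None = None,
                      ) -> RegressionResult | InteractionModel:
    """Balance ratio (AP : TNC+lipids) against % fiber.

    Without diet types: simple OLS on standardized variables (the default
    there; pass ``standardized=False`` to keep raw scales).  With diet
    types: full-interaction linear model (per-type slope and intercept) on
    nonstandardized data by default, reference level = first type in sorted
    order.  See :func:`quasibinomial_ratio_model` for the proportional-scale
    cross-check.
    """
    ratio = np.asarray(ratio, dtype=float)
    fiber = np.asarray(fiber_pct, dtype=float)
    if ratio.shape != fiber.shape:
        raise ValueError("length mismatch between ratio and fiber")
    if diet_type is None:
        if standardized is None or standardized:
            return _ols(standardize(ratio), standardize(fiber))
        return _ols(ratio, fiber)
    labels = pd.Series([str(d) for d in diet_type])
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("interaction model needs >= 2 diet types")
    if standardized:
        ratio = standardize(ratio)
        fiber = standardize(fiber)
    ref = levels[0]
    cols = {"const": np.ones(len(ratio)), "fiber": fiber}
    for lv in levels[1:]:
        d = (labels == lv).to_numpy(float)
        cols[f"[{lv}]"] = d
        cols[f"fiber:[{lv}]"] = fiber * d
    X = pd.DataFrame(cols)
    fit = sm.OLS(ratio, X).fit()
    slopes = {ref: float(fit.params["fiber"])}
    intercepts = {ref: float(fit.params["const"])}
    rows = []
    for lv in levels[1:]:
        slopes[lv] = float(fit.params["fiber"] + fit.params[f"fiber:[{lv}]"])
        intercepts[lv] = float(fit.params["const"] + fit.params[f"[{lv}]"])
        term = f"fiber:[{lv}]"
        rows.append({"term": term, "estimate": float(fit.params[term]),
                     "se": float(fit.bse[term]), "t": float(fit.tvalues[term]),
                     "p": float(fit.pvalues[term])})
    inter_terms = [f"fiber:[{lv}]" for lv in levels[1:]]
    R = np.zeros((len(inter_terms), X.shape[1]))
    for i, term in enumerate(inter_terms):
        R[i, X.columns.get_loc(term)] = 1.0
    joint = fit.f_test(R)
    return InteractionModel(
        reference=ref, slopes=slopes, intercepts=intercepts,
        contrasts=pd.DataFrame(rows), df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared), interaction_p=float(joint.pvalue),
    )


def quasibinomial_ratio_model(ratio, fiber_pct, diet_type=None, *,
                              ratio_max: float = 1.5) -> pd.DataFrame:
    """Quasi-binomial GLM cross-check of :func:`ratio_fiber_model`.

    The balance ratio is a bounded proportion-like quantity; it is rescaled
    to (0, 1) by ``ratio_max`` (default 1.5, the ratio at the extreme corner
    of the observed mixture-triangle range box) and fitted with a logit link;
    dispersion is estimated by Pearson chi-square / df.  Returns the
    coefficient table (term, estimate, se, t, p).
    """
    ratio = np.asarray(ratio, dtype=float)
    fiber = np.asarray(fiber_pct, dtype=float)
    eps = 1e-6
    y = np.clip(ratio / ratio_max, eps, 1 - eps)
    cols = {"const": np.ones(len(y)), "fiber": fiber}
    if diet_type is not None:
        labels = pd.Series([str(d) for d in diet_type])
        for lv in sorted(labels.unique())[1:]:
            d = (labels == lv).to_numpy(float)
            cols[f"[{lv}]"] = d
            cols[f"fiber:[{lv}]"] = fiber * d
    X = pd.DataFrame(cols)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
    return pd.DataFrame({
        "term": X.columns, "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(), "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p (t-distribution, n-2 df).

    Constant columns are an error: correlation is undefined there and the
    caller must drop or handle them explicitly.
    """
    num = table.select_dtypes("number")
    if len(num) < 3:
        raise ValueError("need >= 3 rows for a correlation matrix")
    constant = [c for c in num.columns if num[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    r = num.corr(method="pearson")
    n = len(num)
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 0.0)  # avoid division blowup; diagonal p set below
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    return r, pd.DataFrame(p, index=r.index, columns=r.columns)


def anova_tukey(values, groups, *, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    Tukey comparisons use the studentized-range distribution at the given
    alpha (default 0.05).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if values.shape != labels.shape:
        raise ValueError("length mismatch between values and groups")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    samples = [values[labels == g] for g in uniq]
    F, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    pairwise = pairwise.rename(columns={"p-adj": "p_adj"})
    return AnovaResult(
        F=float(F), df_between=len(uniq) - 1,
        df_within=len(values) - len(uniq), p=float(p),
        group_means={g: float(s.mean()) for g, s in zip(uniq, samples)},
        pairwise=pairwise,
    )


def subpop_ratio_vs_bodymass(subpops: pd.DataFrame, *,
                             ratio_col: str = "mean_ratio",
                             bm_col: str = "mean_calf_bm") -> RegressionResult:
    """OLS of subpopulation mean calf body mass on mean balance ratio."""
    if len(subpops) < 3:
        raise ValueError("need >= 3 subpopulations")
    return _ols(subpops[bm_col].to_numpy(float),
                subpops[ratio_col].to_numpy(float))
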