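"""Balance statistics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rumenbalance import stats as rbs
from rumenbalance import synthetic


# --- standardization -------------------------------------------------------

def test_standardize_simple_and_properties(rng):
    assert rbs.standardize([1, 2, 3]) == pytest.approx([-1, 0, 1])
    z = rbs.standardize(rng.gamma(2, 3, size=200))
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)


def test_standardize_rejects_constant():
    with pytest.raises(ValueError):
        rbs.standardize([5, 5, 5])


# --- isometry test ---------------------------------------------------------

def test_isometry_perfect_fit_degenerate():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    res = rbs.isometry_test(x, x)
    assert res.slope == 1.0
    assert res.t_vs_one == 0.0 and res.p_vs_one == 1.0


def test_isometry_matches_closed_form_ols():
    """Slope equals sum(xy)/sum(x^2) for centered toy data."""
    x = np.array([-1.5, -0.5, 0.5, 1.5])
    y = np.array([-1.2, -0.9, 0.8, 1.3])
    res = rbs.isometry_test(y, x)
    xc, yc = x - x.mean(), y - y.mean()
    slope = (xc * yc).sum() / (xc**2).sum()
    assert res.slope == pytest.approx(slope, abs=1e-12)
    resid = yc - slope * xc
    se = np.sqrt((resid**2).sum() / 2 / (xc**2).sum())
    assert res.slope_se == pytest.approx(se, abs=1e-12)
    assert res.t_vs_one == pytest.approx((slope - 1) / se, abs=1e-10)
    assert res.df == 2 and res.n == 4


def test_isometry_input_checks():
    with pytest.raises(ValueError):
        rbs.isometry_test([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        rbs.isometry_test([1, 2], [1, 2])


def test_slope_equals_pearson_r_on_standardized_data(rng):
    """On z-scored data the OLS slope is the correlation and R^2 = r^2."""
    x = rng.normal(size=300)
    y = 0.7 * x + rng.normal(size=300)
    zx, zy = rbs.standardize(x), rbs.standardize(y)
    res = rbs.isometry_test(zy, zx)
    r = np.corrcoef(x, y)[0, 1]
    assert res.slope == pytest.approx(r, abs=1e-12)
    assert res.r_squared == pytest.approx(r**2, abs=1e-12)


# --- ratio-vs-fiber model --------------------------------------------------

def test_ratio_fiber_exact_linear_toy():
    fiber = np.linspace(20, 70, 30)
    ratio = 2 - 0.02 * fiber
    res = rbs.ratio_fiber_model(ratio, fiber, standardized=False)
    assert res.slope == pytest.approx(-0.02, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)


def test_ratio_fiber_standardized_default_is_correlation(rng):
    fiber = rng.uniform(20, 70, 200)
    ratio = 1.5 - 0.015 * fiber + rng.normal(0, 0.05, 200)
    res = rbs.ratio_fiber_model(ratio, fiber)
    assert res.slope == pytest.approx(np.corrcoef(ratio, fiber)[0, 1],
                                      abs=1e-12)


def test_interaction_model_recovers_per_type_slopes(rng):
    """Known per-diet slopes (-0.9, -0.6, -0.8) recovered within 2 SE."""
    truth = {"broadleaf": -0.9, "conifer": -0.6, "shrub": -0.8}
    rows = []
    for diet, b in truth.items():
        x = rng.uniform(0, 10, 300)
        y = 5 + b * x + rng.normal(0, 1, 300)
        rows.append(pd.DataFrame({"x": x, "y": y, "diet": diet}))
    df = pd.concat(rows)
    m = rbs.ratio_fiber_model(df["y"], df["x"], df["diet"])
    assert m.reference == "broadleaf"
    se = 2 * 1.0 / np.sqrt(300 * np.var(np.linspace(0, 10, 300)))
    for diet, b in truth.items():
        assert m.slopes[diet] == pytest.approx(b, abs=2 * se)
    assert m.interaction_p < 0.01
    assert m.df_resid == 900 - 6


def test_interaction_needs_two_types():
    with pytest.raises(ValueError):
        rbs.ratio_fiber_model([1, 2, 3], [1, 2, 3], ["a", "a", "a"])


def test_quasibinomial_agrees_with_linear_in_sign(rng):
    """The proportional-scale cross-check matches the linear fit's signs."""
    n = 400
    fiber = rng.uniform(20, 70, n)
    diet = rng.choice(["broadleaf", "shrub"], n)
    slope = np.where(diet == "broadleaf", -0.014, -0.008)
    ratio = np.clip(1.4 + slope * fiber + rng.normal(0, 0.06, n), 0.05, 1.45)
    lin = rbs.ratio_fiber_model(ratio, fiber, diet)
    qb = rbs.quasibinomial_ratio_model(ratio, fiber, diet)
    qb = qb.set_index("term")
    assert np.sign(qb.loc["fiber", "estimate"]) == \
        np.sign(lin.slopes[lin.reference])
    lin_sig = lin.contrasts.set_index("term").loc["fiber:[shrub]", "p"] < .05
    qb_sig = qb.loc["fiber:[shrub]", "p"] < .05
    assert lin_sig == qb_sig


# --- correlation matrix ----------------------------------------------------

def test_pearson_matrix_hand_computed():
    tab = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 6.0]})
    r, p = rbs.pearson_matrix(tab)
    # closed form on the 3x2 table
    x, y = tab["a"], tab["b"]
    expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean())**2).sum() * ((y - y.mean())**2).sum())
    assert r.loc["a", "b"] == pytest.approx(expect, abs=1e-12)
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r, r.T)
    t = expect * np.sqrt(1 / (1 - expect**2))
    assert p.loc["a", "b"] == pytest.approx(2 * sps.t.sf(abs(t), 1), abs=1e-12)


def test_pearson_matrix_identical_columns_and_guards():
    tab = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    r, p = rbs.pearson_matrix(tab)
    assert r.loc["a", "b"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        rbs.pearson_matrix(pd.DataFrame({"a": [1., 2., 3.], "c": [5., 5., 5.]}))
    with pytest.raises(ValueError, match=">= 3"):
        rbs.pearson_matrix(tab.iloc[:2])


# --- one-way ANOVA + Tukey -------------------------------------------------

def _brute_force_F(values, labels):
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(values) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def test_anova_F_equals_sum_of_squares_oracle(rng):
    vals = rng.normal(size=40)
    labels = rng.choice(list("abcd"), size=40)
    res = rbs.anova_tukey(vals, labels)
    assert res.F == pytest.approx(_brute_force_F(vals, labels), abs=1e-10)
    assert res.df_between == 3


def test_two_group_anova_F_is_t_squared(rng):
    a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1, 30)
    res = rbs.anova_tukey(np.r_[a, b], ["a"] * 25 + ["b"] * 30)
    t, p = sps.ttest_ind(a, b)
    assert res.F == pytest.approx(t**2, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_anova_type_I_error_near_alpha(rng):
    """Identical group distributions: F-test rejects ~5 % of the time."""
    rej = 0
    reps = 400
    for _ in range(reps):
        vals = rng.normal(size=60)
        labels = np.repeat(list("abc"), 20)
        if sps.f_oneway(*(vals[labels == g] for g in "abc")).pvalue < .05:
            rej += 1
    # binomial 99 % band around 0.05 at 400 reps
    assert 0.02 <= rej / reps <= 0.09


def test_tukey_flags_the_shifted_group(rng):
    """One group shifted by 2 SD (n=50/group) is detected essentially always."""
    hits = 0
    for _ in range(40):
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                     rng.normal(2, 1, 50)]
        labels = np.repeat(list("abc"), 50)
        res = rbs.anova_tukey(vals, labels)
        pw = res.pairwise
        flagged = pw[pw["reject"]]
        involved = set(flagged["group1"]).union(flagged["group2"])
        hits += ("c" in involved
                 and not pw[(pw.group1 == "a") & (pw.group2 == "b")]
                 ["reject"].iloc[0])
    assert hits >= 38  # > 95 % detection


def test_anova_degenerate_grouping():
    with pytest.raises(ValueError):
        rbs.anova_tukey([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        rbs.anova_tukey([1, 2, 3], ["a", "a", "b"])


# --- subpopulation body-mass regression ------------------------------------

def test_subpop_regression_exact_linear():
    tab = pd.DataFrame({"mean_ratio": np.linspace(0.3, 0.9, 10)})
    tab["mean_calf_bm"] = 40 + 30 * tab["mean_ratio"]
    res = rbs.subpop_ratio_vs_bodymass(tab)
    assert res.slope == pytest.approx(30, abs=1e-9)
    assert res.p_vs_zero < 1e-12
    assert res.df == 8


def test_subpop_regression_null_p_uniform(rng):
    """Uncorrelated subpop tables: p-values roughly uniform, |t| small."""
    ps = []
    for _ in range(200):
        tab = pd.DataFrame({"mean_ratio": rng.normal(0.6, 0.1, 30),
                            "mean_calf_bm": rng.normal(65, 4, 30)})
        ps.append(rbs.subpop_ratio_vs_bodymass(tab).p_vs_zero)
    ps = np.array(ps)
    assert 0.35 <= (ps < 0.5).mean() <= 0.65
    assert (ps < 0.05).mean() <= 0.12


def test_subpop_regression_needs_three():
    with pytest.raises(ValueError):
        rbs.subpop_ratio_vs_bodymass(pd.DataFrame(
            {"mean_ratio": [1, 2], "mean_calf_bm": [3, 4]}))
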