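"""Synthetic rumen-sample datasets with realistic correlation structure.

The generator emulates winter rumen-content chemistry of a browsing
ruminant: seven constituents (ash, lignin, microbial-N, available protein,
cellulose, hemicellulose, TNC2+lipids, all % of dm) whose pairwise Pearson
correlations match a published target matrix, a nested population structure
(management areas -> management units -> individuals), diet-type labels,
age-sex classes, sampling dates and calf body masses, plus NIRS-like
spectra for exercising the calibration stage.

Mechanism: the six *measured* constituents are drawn from a Gaussian copula
with the target 6x6 correlation submatrix; the seventh, TNC2+lipids, is
defined by the same subtraction closure used on real data,
``100 - (NDF + AP + ash)``, so closure holds exactly and the TNC2
correlation row is *induced* by the joint distribution of the others.  The
marginal SDs are calibrated (see :func:`calibrate_closure_sds`) so that the
induced row matches its target.  Diet types are attached by ranking
exchangeable subpopulation-level latent effects, which creates the observed
between-diet contrasts (shrub-and-sugar diets highest in microbial-N and
lignin; conifer diets confined to the high-fiber range) without perturbing
the joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .composition import N_TO_PROTEIN, PURINE_TO_MICROBIAL_N

__all__ = [
    "CONSTITUENTS",
    "RUMEN_CORRELATION",
    "SyntheticParams",
    "calibrate_closure_sds",
    "gen_subpop_structure",
    "gen_rumen_samples",
    "gen_spectra",
    "default_basis_bank",
    "gen_standardized_relationship",
    "gen_slope_one_pair",
]

#: Constituent order used throughout (TNC2+lipids last, closure-derived).
CONSTITUENTS = ("ash", "lignin", "microbial_n", "ap",
                "cellulose", "hemicellulose", "tnc2_lipids")

#: The six directly drawn constituents; indices into CONSTITUENTS.
_FREE = CONSTITUENTS[:6]
#: Constituents entering the closure sum 100 - (NDF + AP + ash).
_CLOSURE = ("ash", "lignin", "ap", "cellulose", "hemicellulose")

# Target pairwise Pearson correlations among the seven constituents of
# individual winter rumen samples (n = 481 free-ranging moose).
_R = np.array([
    #  ash   lignin  micN    AP     cell    hemi    tnc2
    [1.000, 0.783, 0.536, 0.750, -0.886, -0.658, 0.720],
    [0.783, 1.000, 0.798, 0.956, -0.962, -0.786, 0.696],
    [0.536, 0.798, 1.000, 0.853, -0.752, -0.669, 0.482],
    [0.750, 0.956, 0.853, 1.000, -0.938, -0.796, 0.640],
    [-0.886, -0.962, -0.752, -0.938, 1.000, 0.780, -0.805],
    [-0.658, -0.786, -0.669, -0.796, 0.780, 1.000, -0.802],
    [0.720, 0.696, 0.482, 0.640, -0.805, -0.802, 1.000],
])
RUMEN_CORRELATION = pd.DataFrame(_R, index=CONSTITUENTS, columns=CONSTITUENTS)

# Marginal SD direction over _CLOSURE solved by calibrate_closure_sds so the
# closure-induced TNC2 correlation row reproduces the target row (<0.01 off);
# overall scale chosen so generated mixture-triangle points span most of the
# observed range box with ~1 % rejection.
_SD_UNIT = {
    "ash": 0.1898687, "lignin": 0.29585671, "ap": 0.34826088,
    "cellulose": 0.84864442, "hemicellulose": 0.18691089,
}
_SD_SCALE = 6.0

# Printed management-area layout: MMA letter -> number of MMUs per diet type.
_MMA_LAYOUT = [
    ("A", "conifer", 3), ("B", "broadleaf", 5), ("C", "conifer", 3),
    ("D", "broadleaf", 4), ("D", "shrub_sugar", 4), ("E", "broadleaf", 4),
    ("E", "shrub_sugar", 1), ("F", "broadleaf", 3), ("G", "shrub_sugar", 3),
]

_AGESEX = ("calf_f", "calf_m", "yearling_f", "yearling_m",
           "adult_f", "adult_m")


def _default_sds() -> dict[str, float]:
    sds = {k: v * _SD_SCALE for k, v in _SD_UNIT.items()}
    sds["microbial_n"] = 0.35
    return sds


@dataclass
class SyntheticParams:
    """Study-condition parameters of the synthetic rumen dataset.

    Defaults reproduce the sampled-population conditions: 481 samples over
    30 subpopulations in 7 management areas, diet types in 16:8:6 proportion
    (broadleaf : shrub-and-sugar : conifer), age-sex mix 52 % calves / 14 %
    yearlings / 20 % adult females / 14 % adult males, ~70:30 early:late
    sampling-date split (inverted in area A), and marginal means closing at
    100 % of dm.
    """

    n_samples: int = 481
    target_correlation: pd.DataFrame = field(
        default_factory=lambda: RUMEN_CORRELATION.copy())
    marginal_means: dict[str, float] = field(default_factory=lambda: {
        "ash": 6.5, "lignin": 16.5, "microbial_n": 1.0, "ap": 13.0,
        "cellulose": 25.5, "hemicellulose": 15.0})
    marginal_sds: dict[str, float] = field(default_factory=_default_sds)
    #: intraclass correlation of the latent field at subpopulation level
    subpop_icc: float = 0.3
    #: None: 30 units up to the study's sampling density (~16 samples per
    #: unit), then grown proportionally so density stays realistic
    n_subpops: int | None = None
    min_per_subpop: int = 5
    diet_type_probs: tuple[float, float, float] = (16 / 30, 8 / 30, 6 / 30)
    #: optional additive (% dm) shifts {diet: {constituent: shift}}; nonzero
    #: shifts add variance outside the target correlation structure
    diet_effects: dict[str, dict[str, float]] | None = None
    agesex_probs: tuple[float, ...] = (0.246, 0.289, 0.080, 0.060, 0.191, 0.134)
    calf_bm_mean: float = 65.0
    calf_bm_sd: float = 7.0
    calf_bm_subpop_sd: float = 4.0
    #: injected slope of subpop mean calf BM on subpop mean balance ratio
    #: (kg per ratio unit); 0 = the null of no relationship
    bm_ratio_slope: float = 0.0
    #: fraction of total N that is available (splits total N into ADF-N)
    digestible_n_fraction: float = 0.8
    #: mixture-triangle acceptance box: (AP, TNC, fiber) as % of macronutrients
    range_box: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "ap": (7.0, 36.0), "tnc": (24.0, 48.0), "fiber": (16.0, 69.0)})
    early_late_split: float = 0.7

    def __post_init__(self) -> None:
        if abs(sum(self.diet_type_probs) - 1.0) > 1e-9:
            raise ValueError("diet_type_probs must sum to 1")
        if abs(sum(self.agesex_probs) - 1.0) > 1e-9:
            raise ValueError("agesex_probs must sum to 1")
        R = self.target_correlation.to_numpy()
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("target_correlation must be symmetric with "
                             "unit diagonal")
        self.target_correlation = pd.DataFrame(
            _nearest_corr(R), index=self.target_correlation.index,
            columns=self.target_correlation.columns)


def _nearest_corr(R: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to PSD by eigenvalue clipping."""
    w, V = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    w = np.clip(w, floor, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def calibrate_closure_sds(target: pd.DataFrame = RUMEN_CORRELATION, *,
                          n_restarts: int = 40, seed: int = 0,
                          ) -> dict[str, float]:
    """Solve for marginal-SD proportions consistent with the closure.

    With ``tnc2 = 100 - sum(closure constituents)``, the correlation row of
    TNC2 is a deterministic function of the closure constituents' SDs and
    their correlation submatrix.  This solves (multi-start Nelder-Mead) for
    the unit-norm SD vector whose induced row matches the target row; the
    packaged defaults were produced by this function.
    """
    R6 = target.loc[list(_FREE), list(_FREE)].to_numpy()
    t_row = target.loc["tnc2_lipids", list(_FREE)].to_numpy()
    idx = [list(_FREE).index(c) for c in _CLOSURE]

    def induced(sig: np.ndarray) -> np.ndarray:
        cov_t = -np.einsum("a,aj->j", sig, R6[idx, :])
        var_t = sig @ R6[np.ix_(idx, idx)] @ sig
        return cov_t / np.sqrt(var_t)

    def loss(logsig: np.ndarray) -> float:
        return float(((induced(np.exp(logsig)) - t_row) ** 2).sum())

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        res = minimize(loss, rng.normal(0, 1, len(idx)), method="Nelder-Mead",
                       options=dict(maxiter=20000, xatol=1e-10, fatol=1e-14))
        if best is None or res.fun < best.fun:
            best = res
    sig = np.exp(best.x)
    sig /= np.linalg.norm(sig)
    return dict(zip(_CLOSURE, sig))


def _resolve_n_subpops(params: SyntheticParams) -> int:
    """30 units at study scale; grown with n to keep ~16 samples per unit.

    Subpopulation-level variation only averages out if the number of units
    grows with the sample, so very large simulated datasets keep the study's
    per-unit sampling density instead of piling samples into 30 units.
    """
    if params.n_subpops is not None:
        return params.n_subpops
    return max(30, round(params.n_samples / 16))


def gen_subpop_structure(params: SyntheticParams | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Subpopulation (MMU) table: id, management area, diet type.

    With the default 30 subpopulations the printed area layout is used
    (broadleaf in B/D/E/F, shrub-and-sugar in G/D/E, conifer in A/C);
    otherwise diet types are drawn from ``diet_type_probs`` and areas
    assigned round-robin.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    n_subpops = _resolve_n_subpops(params)
    rows = []
    if n_subpops == 30:
        for mma, diet, k in _MMA_LAYOUT:
            for _ in range(k):
                rows.append({"mma": mma, "diet_type": diet})
    else:
        diets = rng.choice(["broadleaf", "shrub_sugar", "conifer"],
                           size=n_subpops, p=params.diet_type_probs)
        for i, diet in enumerate(diets):
            rows.append({"mma": "ABCDEFG"[i % 7], "diet_type": diet})
    df = pd.DataFrame(rows)
    df.insert(0, "mmu", [f"{r.mma}{i + 1:02d}" for i, r in df.iterrows()])
    return df


def _assign_subpop_effects(z_sub: np.ndarray, subpops: pd.DataFrame,
                           rng: np.random.Generator) -> np.ndarray:
    """Permute exchangeable subpop effects to match diet-type contrasts.

    Shrub-and-sugar units receive the highest lignin + microbial-N latent
    effects; conifer units the highest fiber effects among the rest.  A
    permutation of i.i.d. draws leaves the sample distribution unchanged.
    """
    diet = subpops["diet_type"].to_numpy()
    n = len(diet)
    i_lig, i_mic = _FREE.index("lignin"), _FREE.index("microbial_n")
    i_cel, i_hem = _FREE.index("cellulose"), _FREE.index("hemicellulose")
    order = np.argsort(-(z_sub[:, i_lig] + z_sub[:, i_mic]))
    n_shrub = int((diet == "shrub_sugar").sum())
    shrub_pool = order[:n_shrub]
    rest = order[n_shrub:]
    fiber_score = z_sub[rest, i_cel] + z_sub[rest, i_hem]
    rest = rest[np.argsort(-fiber_score)]
    n_conifer = int((diet == "conifer").sum())
    conifer_pool, broad_pool = rest[:n_conifer], rest[n_conifer:]
    out = np.empty(n, dtype=int)
    for pool, name in ((shrub_pool, "shrub_sugar"),
                       (conifer_pool, "conifer"),
                       (broad_pool, "broadleaf")):
        slots = np.flatnonzero(diet == name)
        out[slots] = rng.permutation(pool)
    return z_sub[out]


def _season_dates(rng: np.random.Generator, mma: np.ndarray,
                  split: float) -> np.ndarray:
    """ISO dates over the hunting season, early:late per area."""
    early = pd.date_range("2014-10-13", "2014-11-30").to_numpy()
    late = pd.date_range("2014-12-01", "2015-02-22").to_numpy()
    p_early = np.where(mma == "A", 1.0 - split, split)
    take_early = rng.random(len(mma)) < p_early
    dates = np.where(take_early,
                     rng.choice(early, size=len(mma)),
                     rng.choice(late, size=len(mma)))
    return np.array([str(pd.Timestamp(d).date()) for d in dates])


def gen_rumen_samples(params: SyntheticParams | None = None, seed: int = 0,
                      ) -> pd.DataFrame:
    """Generate a full synthetic rumen-sample table.

    Returns one row per sample with raw proximate columns (ash, total_n,
    adf_n, ndf, adf, lignin, purine_marker), the derived constituents, and
    metadata (mma, mmu, diet_type, age_class, sex, date, body_mass).
    Closure ``ap + ndf + ash + tnc2_lipids = 100`` holds for every record;
    bit-identical output for identical seed.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    R6 = params.target_correlation.loc[list(_FREE), list(_FREE)].to_numpy()
    L = np.linalg.cholesky(_nearest_corr(R6))
    mu = np.array([params.marginal_means[c] for c in _FREE])
    sd = np.array([params.marginal_sds[c] for c in _FREE])
    if mu[[0, 1, 3, 4, 5]].sum() >= 100:
        raise ValueError("infeasible marginal means: closure impossible "
                         "(measured constituents already sum to >= 100)")

    subpops = gen_subpop_structure(params, seed=seed)
    n_sub = len(subpops)
    base = params.min_per_subpop
    if base * n_sub > params.n_samples:
        raise ValueError("n_samples too small for min_per_subpop")
    extra = rng.multinomial(params.n_samples - base * n_sub,
                            np.full(n_sub, 1.0 / n_sub))
    sizes = base + extra
    sub_idx = np.repeat(np.arange(n_sub), sizes)
    n = params.n_samples

    z_sub = rng.standard_normal((n_sub, 6)) @ L.T
    z_sub = _assign_subpop_effects(z_sub, subpops, rng)
    icc = params.subpop_icc
    shift = np.zeros((n, 6))
    if params.diet_effects:
        diets = subpops["diet_type"].to_numpy()[sub_idx]
        for d, eff in params.diet_effects.items():
            mask = diets == d
            for c, v in eff.items():
                shift[mask, _FREE.index(c)] += v

    box = params.range_box
    X = np.empty((n, 6))
    pending = np.arange(n)
    for _ in range(200):
        z_ind = rng.standard_normal((len(pending), 6)) @ L.T
        z = (np.sqrt(icc) * z_sub[sub_idx[pending]]
             + np.sqrt(1 - icc) * z_ind)
        cand = mu + sd * z + shift[pending]
        tnc2 = 100.0 - cand[:, [0, 1, 3, 4, 5]].sum(axis=1)
        ap, cell, hemi = cand[:, 3], cand[:, 4], cand[:, 5]
        macro = ap + cell + hemi + tnc2
        ap_p = 100 * ap / macro
        tnc_p = 100 * tnc2 / macro
        fib_p = 100 * (cell + hemi) / macro
        ok = ((cand > 0).all(axis=1) & (tnc2 > 0)
              & (ap_p >= box["ap"][0]) & (ap_p <= box["ap"][1])
              & (tnc_p >= box["tnc"][0]) & (tnc_p <= box["tnc"][1])
              & (fib_p >= box["fiber"][0]) & (fib_p <= box["fiber"][1]))
        X[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        raise ValueError("infeasible marginals: rejection sampling did not "
                         "converge inside the range box")

    cols = dict(zip(_FREE, X.T))
    df = pd.DataFrame(cols)
    df["tnc2_lipids"] = 100.0 - df[list(_CLOSURE)].sum(axis=1)

    # proximate-scale raw measurements consistent with the constituents
    f = params.digestible_n_fraction
    avail_n = df["ap"] / N_TO_PROTEIN
    df["total_n"] = avail_n / f
    df["adf_n"] = df["total_n"] - avail_n
    df["ndf"] = df["lignin"] + df["cellulose"] + df["hemicellulose"]
    df["adf"] = df["lignin"] + df["cellulose"]
    df["purine_marker"] = df["microbial_n"] / PURINE_TO_MICROBIAL_N

    # metadata
    df["mmu"] = subpops["mmu"].to_numpy()[sub_idx]
    df["mma"] = subpops["mma"].to_numpy()[sub_idx]
    df["diet_type"] = subpops["diet_type"].to_numpy()[sub_idx]
    agesex = rng.choice(_AGESEX, size=n, p=params.agesex_probs)
    df["age_class"] = [a.rsplit("_", 1)[0] for a in agesex]
    df["sex"] = [a.rsplit("_", 1)[1] for a in agesex]
    df["date"] = _season_dates(rng, df["mma"].to_numpy(),
                               params.early_late_split)

    # calf body mass: subpop effect + optional injected ratio dependence
    ratio = (100 * df["ap"] / (df["ap"] + df["cellulose"]
             + df["hemicellulose"] + df["tnc2_lipids"])) / \
            (100 * df["tnc2_lipids"] / (df["ap"] + df["cellulose"]
             + df["hemicellulose"] + df["tnc2_lipids"]))
    sub_ratio = ratio.groupby(sub_idx).mean()
    sub_bm = (params.calf_bm_mean
              + params.calf_bm_subpop_sd * rng.standard_normal(n_sub)
              + params.bm_ratio_slope * (sub_ratio - sub_ratio.mean()))
    bm = sub_bm.to_numpy()[sub_idx] + params.calf_bm_sd * rng.standard_normal(n)
    scale = {"calf": 1.0, "yearling": 2.0, "adult": 2.7}
    df["body_mass"] = np.round(
        bm * np.array([scale[a] for a in df["age_class"]]), 1)

    df.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# NIRS-like spectra


def default_basis_bank(wavelengths: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Deterministic nonnegative component spectra, one per constituent.

    The grid mimics a bench NIR instrument's 780-2498 nm range at reduced
    resolution (4 nm).  Each component spectrum is a fixed sum of Gaussian
    absorption bands; returns ``(wavelengths, basis)`` with the basis
    indexed by constituent.
    """
    if wavelengths is None:
        wavelengths = np.arange(780.0, 2499.0, 4.0)
    centers = {
        "ash": [(1100, 60, 0.9), (2100, 120, 0.5)],
        "lignin": [(1450, 80, 1.0), (1930, 70, 0.6)],
        "microbial_n": [(1510, 50, 0.8), (2050, 90, 0.7)],
        "ap": [(1650, 70, 1.0), (2180, 60, 0.8)],
        "cellulose": [(1490, 100, 0.7), (2270, 80, 1.0)],
        "hemicellulose": [(1720, 90, 0.9), (2330, 70, 0.6)],
        "tnc2_lipids": [(980, 70, 0.6), (1780, 110, 1.0)],
    }
    rows = {}
    for name, bands in centers.items():
        s = np.zeros_like(wavelengths)
        for c, w, a in bands:
            s += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
        rows[name] = s
    return wavelengths, pd.DataFrame(rows).T


def gen_spectra(profiles: pd.DataFrame,
                basis_bank: pd.DataFrame | None = None,
                noise_sd: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Linear-mixture spectra: composition-weighted basis + baseline + noise.

    ``profiles`` must contain one column per basis constituent (% of dm).
    At zero noise a one-hot composition returns (a scaled copy of) the pure
    component spectrum and mixing is exactly linear.
    """
    if basis_bank is None:
        _, basis_bank = default_basis_bank()
    missing = [c for c in basis_bank.index if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack basis constituents: {missing}")
    W = profiles[list(basis_bank.index)].to_numpy(float) / 100.0
    if W.shape[1] != basis_bank.shape[0]:
        raise ValueError("composition/basis dimension mismatch")
    rng = np.random.default_rng(seed)
    baseline = 0.05 + 1e-5 * np.arange(basis_bank.shape[1])
    S = W @ basis_bank.to_numpy() + baseline
    S = S + noise_sd * rng.standard_normal(S.shape)
    cols = [f"w{int(w)}" for w in
            np.arange(780.0, 2499.0, 4.0)[:basis_bank.shape[1]]]
    return pd.DataFrame(S, index=profiles.index, columns=cols)


# ---------------------------------------------------------------------------
# Known-truth bivariate helpers for slope-recovery and calibration tests


def gen_standardized_relationship(n: int, slope: float, seed: int = 0,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Population-standardized pair with OLS slope = ``slope``.

    Both margins have unit variance, so the population regression slope
    equals the correlation; requires ``|slope| < 1``.
    """
    if not abs(slope) < 1:
        raise ValueError("standardized slope must satisfy |slope| < 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = slope * x + np.sqrt(1 - slope**2) * rng.standard_normal(n)
    return x, y


def gen_slope_one_pair(n: int, r: float, seed: int = 0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate pair with true regression slope 1 and correlation ``r``.

    ``y = x + e`` with the noise SD set so that corr(x, y) = r; the null
    case for calibrating the slope-equals-one test.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = x + np.sqrt(1.0 / r**2 - 1.0) * rng.standard_normal(n)
    return x, y
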