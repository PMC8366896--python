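"""Input validation, configuration and the end-to-end analysis pipeline.

The canonical input is a UTF-8 comma-separated table with a header row
(decimal points, ISO-8601 dates):

    sample_id, ash, total_n, adf_n, ndf, adf, lignin, lipids, sugars,
    starch, purine_marker, mma, mmu, age_class, sex, body_mass, date,
    diet_type

Optional columns may be absent.  The pipeline derives macronutrient
profiles, projects them into the mixture triangle, runs the statistical
battery, and writes CSV/JSON outputs plus a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, composition, rmt, stats

__all__ = ["PipelineConfig", "validate_input", "read_samples",
           "run_pipeline"]

_NUMERIC_COLS = ("ash", "total_n", "adf_n", "ndf", "adf", "lignin", "lipids",
                 "sugars", "starch", "purine_marker", "body_mass")


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the standard analysis filters.

    Sample-based analyses (projection, pooled regressions) use every
    sample; subpopulation-level analyses keep only units with at least
    ``min_per_subpop`` samples collected on or after ``date_filter``.
    """

    input_csv: str = ""
    output_dir: str = "rumenbalance_out"
    date_filter: str | None = "2014-10-23"
    min_per_subpop: int = 5
    standardized_interaction: bool = False
    ratio_max: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def validate_input(path: str | Path) -> pd.DataFrame:
    """Schema/consistency check of an input CSV; returns the issue table.

    Each issue row carries the offending row number and a reason.  A clean
    file yields an empty table.  Decimal commas are a hard error naming the
    dialect, not an issue row.
    """
    df = _read_raw(path)
    issues = []
    for col in composition._REQUIRED_COLS:
        if col not in df.columns:
            issues.append({"row": -1, "sample_id": "",
                           "reason": f"missing required column {col!r}"})
    if issues:
        return pd.DataFrame(issues)
    _, report = composition.derive_profiles(df)
    return report[["row", "sample_id", "reason"]]


def _read_raw(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    for col in df.columns:
        if col in _NUMERIC_COLS and df[col].dtype == object:
            if df[col].astype(str).str.contains(",").any():
                raise ValueError(
                    f"column {col!r} contains decimal commas; inputs must "
                    "use the point-decimal CSV dialect")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and type-coerce a samples CSV (no validation beyond dialect)."""
    df = _read_raw(path)
    for col in _NUMERIC_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write results under ``output_dir``.

    Stages: derive profiles -> mixture-triangle projection -> pooled
    isometry and ratio-vs-fiber models (interaction + quasi-binomial
    cross-check when diet types are present) -> constituent correlation
    matrix -> age-sex ANOVAs -> subpopulation body-mass regression.
    Returns the report bundle; partial outputs are never written silently
    (any failure propagates before files appear).
    """
    samples = read_samples(config.input_csv)
    profiles, report = composition.derive_profiles(samples)
    if profiles.empty:
        raise ValueError("no valid samples after validation")
    meta_cols = [c for c in ("sample_id", "mma", "mmu", "age_class", "sex",
                             "body_mass", "date", "diet_type")
                 if c in samples.columns]
    merged = profiles.merge(samples[meta_cols], on="sample_id", how="left")

    pts = [rmt.to_rmt_xy(r.ap, r.fiber, r.tnc2_lipids)
           for r in merged.itertuples()]
    merged["rmt_x"] = [p.x for p in pts]
    merged["rmt_y"] = [p.y for p in pts]
    merged["rmt_i"] = [p.i for p in pts]
    merged["balance_ratio"] = [rmt.balance_ratio(p) for p in pts]

    results: dict = {"n_samples": int(len(merged))}
    rng_box = rmt.observed_range(pts)
    results["observed_range"] = {k: list(v) for k, v in rng_box.items()}

    iso = stats.isometry_test(stats.standardize(merged["rmt_y"]),
                              stats.standardize(merged["rmt_x"]))
    results["isometry"] = _reg_dict(iso)

    # restricted set for models and subpopulation analyses
    sub = merged
    if config.date_filter and "date" in merged.columns:
        sub = merged[pd.to_datetime(merged["date"])
                     >= pd.Timestamp(config.date_filter)]
    if "mmu" in sub.columns:
        counts = sub.groupby("mmu")["sample_id"].count()
        keep = counts[counts >= config.min_per_subpop].index
        sub = sub[sub["mmu"].isin(keep)]

    fit = stats.ratio_fiber_model(sub["balance_ratio"], sub["rmt_i"])
    results["ratio_fiber"] = _reg_dict(fit)
    if "diet_type" in sub.columns and sub["diet_type"].notna().any():
        labelled = sub[sub["diet_type"].notna()]
        if labelled["diet_type"].nunique() >= 2:
            inter = stats.ratio_fiber_model(
                labelled["balance_ratio"], labelled["rmt_i"],
                labelled["diet_type"],
                standardized=config.standardized_interaction)
            results["ratio_fiber_interaction"] = {
                "reference": inter.reference, "slopes": inter.slopes,
                "intercepts": inter.intercepts,
                "interaction_p": inter.interaction_p,
                "r_squared": inter.r_squared,
                "contrasts": inter.contrasts.to_dict("records"),
            }
            qb = stats.quasibinomial_ratio_model(
                labelled["balance_ratio"], labelled["rmt_i"],
                labelled["diet_type"], ratio_max=config.ratio_max)
            results["ratio_fiber_quasibinomial"] = qb.to_dict("records")

    corr_cols = [c for c in ("ash", "lignin", "microbial_n", "ap",
                             "cellulose", "hemicellulose", "tnc2_lipids")
                 if c in merged.columns and merged[c].notna().all()]
    r, p = stats.pearson_matrix(merged[corr_cols])
    results["constituent_correlations"] = r.round(4).to_dict()

    if {"age_class", "sex"} <= set(merged.columns):
        merged["agesex"] = merged["age_class"] + "_" + merged["sex"]
        anovas = {}
        for col in corr_cols:
            try:
                a = stats.anova_tukey(merged[col], merged["agesex"])
            except ValueError:
                continue
            anovas[col] = {"F": a.F, "p": a.p,
                           "df": [a.df_between, a.df_within]}
        results["agesex_anova"] = anovas

    if {"mmu", "body_mass", "age_class"} <= set(merged.columns):
        calves = sub[sub["age_class"] == "calf"] if "age_class" in sub else sub
        tab = (sub.groupby("mmu")
               .agg(mean_ratio=("balance_ratio", "mean")))
        bm = (calves.groupby("mmu")
              .agg(mean_calf_bm=("body_mass", "mean")))
        tab = tab.join(bm, how="inner").dropna()
        if len(tab) >= 3:
            reg = stats.subpop_ratio_vs_bodymass(tab)
            results["subpop_bm_vs_ratio"] = _reg_dict(reg)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged.to_csv(outdir / "derived_profiles.csv", index=False)
    report.to_csv(outdir / "validation_report.csv", index=False)
    results["provenance"] = {
        "package_version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results


def _reg_dict(r: stats.RegressionResult) -> dict:
    return {"slope": r.slope, "intercept": r.intercept,
            "slope_se": r.slope_se, "t_vs_zero": r.t_vs_zero,
            "p_vs_zero": r.p_vs_zero, "t_vs_one": r.t_vs_one,
            "p_vs_one": r.p_vs_one, "r_squared": r.r_squared,
            "df": r.df, "n": r.n}
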