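"""The winter foodscape: packaged forage and feed composition analyses.

Ships the mean winter composition of the 12 most-eaten food plants
(together ~85 % of ingested dry matter) as a versioned fixture, plus a
clearly marked synthetic stand-in table for five common supplementary
feeds, and provides the correlation, PCA and mixture-triangle analyses of
that food environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import composition, rmt, stats

__all__ = [
    "PCAResult",
    "load_plants",
    "load_feeds",
    "PLANT_PCA_CONSTITUENTS",
    "PLANT_PCA_CONSTITUENTS_NO_LIPIDS",
    "plant_correlations",
    "plant_pca",
    "feed_comparison_pca",
    "plant_nutritional_space",
]

#: Default constituent list for the plant PCA.
PLANT_PCA_CONSTITUENTS = ("lignin", "cellulose", "hemicellulose", "ap",
                          "tnc1", "dndf", "lipids")
#: Six-constituent variant (lipids dropped).
PLANT_PCA_CONSTITUENTS_NO_LIPIDS = PLANT_PCA_CONSTITUENTS[:-1]

_CORR_CONSTITUENTS = ("lignin", "cellulose", "hemicellulose", "ap",
                      "tnc1", "lipids")


@dataclass(frozen=True)
class PCAResult:
    """Loadings (constituents x PCs), scores (items x PCs) and variance
    fractions of a correlation-matrix PCA."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray


def load_plants() -> pd.DataFrame:
    """The 12-species winter forage table (% of dm, printed 1-decimal values).

    Columns: species, n_sampled, twig_diameter (mm), cp, ap, tnc1, lipids,
    lignin, cellulose, hemicellulose, ndf, dndf.
    """
    with resources.files("rumenbalance.data").joinpath(
            "plants_winter.csv").open() as fh:
        return pd.read_csv(fh)


def load_feeds(path=None) -> pd.DataFrame:
    """Supplementary-feed composition (ap, ndf, sugars, starch; % of dm).

    The packaged default is a *synthetic stand-in*: only the dominant
    sugar/starch contents of the three root vegetables are published
    anchors; the other entries are plausible constructed values and can be
    overridden by passing a CSV path with the same columns.
    """
    if path is not None:
        df = pd.read_csv(path)
    else:
        with resources.files("rumenbalance.data").joinpath(
                "feeds_synthetic.csv").open() as fh:
            df = pd.read_csv(fh)
    missing = [c for c in ("feed", "ap", "ndf", "sugars", "starch")
               if c not in df.columns]
    if missing:
        raise ValueError(f"feed table missing columns: {missing}")
    if df[["ap", "ndf", "sugars", "starch"]].isna().any().any():
        gaps = df.columns[df.isna().any()].tolist()
        raise ValueError(f"feed table has missing values in: {gaps}")
    df["tnc1"] = [composition.tnc1(s, st)
                  for s, st in zip(df["sugars"], df["starch"])]
    return df


def plant_correlations() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p over six constituents of the 12 plant species.

    Same code path as :func:`rumenbalance.stats.pearson_matrix`.
    """
    plants = load_plants()
    return stats.pearson_matrix(plants[list(_CORR_CONSTITUENTS)])


def _corr_pca(table: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix with a deterministic sign convention."""
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant constituent column in PCA input")
    Z = (X - X.mean(axis=0)) / sd
    # eigendecomposition of the correlation matrix; descending variance
    C = np.corrcoef(Z, rowvar=False) if table.shape[1] > 1 else np.ones((1, 1))
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    pcs = [f"PC{j + 1}" for j in range(V.shape[1])]
    loadings = pd.DataFrame(V, index=table.columns, columns=pcs)
    scores = pd.DataFrame(Z @ V, index=table.index, columns=pcs)
    return PCAResult(loadings=loadings, scores=scores,
                     variance_explained=w / w.sum())


def plant_pca(constituents=PLANT_PCA_CONSTITUENTS) -> PCAResult:
    """Correlation-matrix PCA of the 12 plant species.

    The constituents are standardized (the table mixes scales); pass
    :data:`PLANT_PCA_CONSTITUENTS_NO_LIPIDS` for the six-constituent
    variant.
    """
    plants = load_plants()
    unknown = [c for c in constituents if c not in plants.columns]
    if unknown:
        raise ValueError(f"unknown constituents: {unknown}")
    if len(constituents) < 1:
        raise ValueError("need at least one constituent")
    table = plants.set_index("species")[list(constituents)]
    return _corr_pca(table)


def feed_comparison_pca(feed_table: pd.DataFrame | None = None,
                        ) -> PCAResult:
    """Joint PCA of the 12 plants and 5 supplementary feeds.

    Restricted to the three constituents available for the feeds: available
    protein, total NDF and TNC.
    """
    feeds = feed_table if feed_table is not None else load_feeds()
    plants = load_plants()
    a = plants.set_index("species")[["ap", "ndf", "tnc1"]]
    b = feeds.set_index("feed")[["ap", "ndf", "tnc1"]]
    return _corr_pca(pd.concat([a, b]))


def plant_nutritional_space(species=None) -> rmt.NutritionalSpace:
    """Convex nutritional space of the forage plants in the mixture triangle.

    Projects each plant (x = TNC1 + lipids, y = AP, implicit = cellulose +
    hemicellulose) and hulls the points; ``species`` restricts to a subset.
    """
    plants = load_plants()
    if species is not None:
        plants = plants[plants["species"].isin(list(species))]
    pts = [rmt.to_rmt_xy(r.ap, r.cellulose + r.hemicellulose,
                         r.tnc1 + r.lipids, source_kind="plant")
           for r in plants.itertuples()]
    return rmt.nutritional_space(pts)
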