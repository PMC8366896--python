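"""Simplified chemometric calibration of NIR spectra.

Two stages mirror standard lab practice: (1) pick a representative subset
of scanned samples for expensive wet chemistry, by distance from the data
center in the space of the first three principal components of the
spectra; (2) fit a latent-variable (PLS) regression of constituent
concentrations on spectra, choosing the component count by cross-validated
RMSE, and report prediction error (RMSEP) and R-squared on held-out
samples.

PLS here is the standard NIPALS latent-variable regression; an orthogonal
signal-correction refinement would change interpretability of the
components, not the prediction contract this module is tested on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = ["CalibrationModel", "select_representative",
           "fit_calibration", "evaluate"]


@dataclass
class CalibrationModel:
    """Fitted latent-variable calibration for one or more constituents."""

    n_components: int
    constituents: tuple[str, ...]
    pls: PLSRegression
    training_rmse: dict[str, float]
    cv_trace: pd.DataFrame  # n_components, cv_rmse

    def predict(self, spectra: pd.DataFrame) -> pd.DataFrame:
        Y = self.pls.predict(np.asarray(spectra, dtype=float))
        return pd.DataFrame(Y, index=spectra.index, columns=self.constituents)

    def to_json(self) -> str:
        return json.dumps({
            "format_version": 1,
            "n_components": self.n_components,
            "constituents": list(self.constituents),
            "coef": np.asarray(self.pls.coef_).tolist(),
            "x_mean": self.pls._x_mean.tolist(),
            "y_mean": self.pls._y_mean.tolist(),
            "training_rmse": self.training_rmse,
        })


def select_representative(spectra: pd.DataFrame, k: int) -> np.ndarray:
    """Indices of ``k`` samples spanning the spectral variation.

    Standardized spectra are reduced to three principal components and
    whitened (Mahalanobis metric in score space).  Selection starts from
    the sample farthest from the data center and proceeds Kennard-Stone
    style: each further pick maximizes its minimum distance to the samples
    already selected, so the extremes enter first and the remaining picks
    stratify the occupied score space.  Ties break by index order, so one
    member of a duplicated pair is selected before both.
    """
    X = np.asarray(spectra, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == n:
        return np.arange(n)
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=min(3, n - 1, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z) / np.sqrt(pca.explained_variance_)
    d_center = (scores**2).sum(axis=1)
    first = int(np.lexsort((np.arange(n), -d_center))[0])
    chosen = [first]
    d_min = np.linalg.norm(scores - scores[first], axis=1)
    d_min[first] = -np.inf
    while len(chosen) < k:
        nxt = int(np.lexsort((np.arange(n), -d_min))[0])
        chosen.append(nxt)
        d_min = np.minimum(d_min,
                           np.linalg.norm(scores - scores[nxt], axis=1))
        d_min[nxt] = -np.inf
    return np.array(sorted(chosen))


def fit_calibration(spectra_train: pd.DataFrame, y_train: pd.DataFrame,
                    max_components: int = 10, *,
                    cv_folds: int | None = 5) -> CalibrationModel:
    """PLS calibration with cross-validated component selection.

    The component count minimizing CV RMSE (k-fold, or leave-one-out when
    ``cv_folds`` is None or exceeds n) is chosen; the count is capped by
    the data rank.
    """
    X = np.asarray(spectra_train, dtype=float)
    Y = pd.DataFrame(y_train)
    n = len(X)
    cap = min(max_components, n - 2, X.shape[1])
    if cap < 1:
        raise ValueError("too few training samples for calibration")
    if cv_folds is None or cv_folds >= n:
        splitter = LeaveOneOut()
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=False)
    yv = Y.to_numpy(float)
    trace = []
    for nc in range(1, cap + 1):
        errs = []
        for tr, te in splitter.split(X):
            m = PLSRegression(n_components=min(nc, len(tr) - 1), scale=False)
            m.fit(X[tr], yv[tr])
            errs.append(((m.predict(X[te]) - yv[te]) ** 2).mean())
        trace.append({"n_components": nc,
                      "cv_rmse": float(np.sqrt(np.mean(errs)))})
    trace = pd.DataFrame(trace)
    best = int(trace.loc[trace["cv_rmse"].idxmin(), "n_components"])
    pls = PLSRegression(n_components=best, scale=False)
    pls.fit(X, yv)
    resid = pls.predict(X) - yv
    rmse = {c: float(np.sqrt((resid[:, j] ** 2).mean()))
            for j, c in enumerate(Y.columns)}
    return CalibrationModel(n_components=best,
                            constituents=tuple(str(c) for c in Y.columns),
                            pls=pls, training_rmse=rmse, cv_trace=trace)


def evaluate(model: CalibrationModel, spectra_test: pd.DataFrame,
             y_test: pd.DataFrame) -> pd.DataFrame:
    """Prediction metrics per constituent: RMSEP (constituent scale) and R².

    R² <= 0 flags a predictor no better than the test-set mean.  Invariant
    to test-set ordering.
    """
    Y = pd.DataFrame(y_test)
    if len(Y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(pd.DataFrame(spectra_test))
    rows = []
    for c in model.constituents:
        err = pred[c].to_numpy() - Y[c].to_numpy(float)
        rmsep = float(np.sqrt((err**2).mean()))
        ss_tot = float(((Y[c] - Y[c].mean()) ** 2).sum())
        r2 = 1.0 - float((err**2).sum()) / ss_tot if ss_tot > 0 else np.nan
        rows.append({"constituent": c, "rmsep": rmsep, "r_squared": r2,
                     "degenerate": bool(r2 <= 0) if ss_tot > 0 else True})
    return pd.DataFrame(rows)
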