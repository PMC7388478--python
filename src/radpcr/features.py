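"""Patch-to-subject feature aggregation and variance-thresholded PCA.

Two aggregation routes are provided:

``mean``
    Average each subject's patch vectors, then (optionally) fit PCA on the
    subject-level matrix.
``pca_then_mean`` (default)
    Fit PCA on the patch-level matrix, project every patch, and average each
    subject's patch *scores*.  This is the route that can retain more
    components than the subject count, since the PCA sees one row per patch.

The retention rule keeps the smallest number of leading components whose
cumulative explained-variance ratio reaches the threshold (default 0.95).
Component signs are fixed so each loading's largest-magnitude entry is
positive, making loadings reproducible across platforms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, FitError, SchemaError
from .patch_sampling import Patch, patches_to_matrix

__all__ = [
    "PCAModel",
    "aggregate_subject_features",
    "fit_pca",
    "transform_pca",
    "subject_pc_scores",
    "save_pca_model",
    "load_pca_model",
]


@dataclass
class PCAModel:
    """Centered PCA with a variance-threshold retention rule.

    Attributes
    ----------
    mean : (p,) centering vector
    loadings : (m_total, p) orthonormal rows, ordered by decreasing variance
    evr : (m_total,) explained-variance ratios (sum <= 1)
    retained : smallest m with cumulative evr >= tau
    tau : retention threshold used at fit time
    """

    mean: np.ndarray
    loadings: np.ndarray
    evr: np.ndarray
    retained: int
    tau: float

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.retained)]


def aggregate_subject_features(
    patches: Sequence[Patch],
    mode: Literal["mean"] = "mean",
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate patch vectors to one row per subject.

    Returns a (subjects x features) frame indexed by subject_id, plus the
    aligned label series.  Subject order follows first appearance.
    """
    if mode != "mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if not patches:
        raise AggregationError("no patches supplied")
    X, meta = patches_to_matrix(patches)
    order: list[str] = []
    for sid in meta["subject_id"]:
        if sid not in order:
            order.append(sid)
    rows, labels = [], []
    for sid in order:
        sel = (meta["subject_id"] == sid).to_numpy()
        if not sel.any():
            raise AggregationError(f"subject {sid!r} has no patches")
        rows.append(X[sel].mean(axis=0))
        labels.append(int(meta.loc[sel, "label"].iloc[0]))
    cols = [f"v{j}" for j in range(X.shape[1])]
    frame = pd.DataFrame(np.stack(rows), index=pd.Index(order, name="subject_id"), columns=cols)
    return frame, pd.Series(labels, index=frame.index, name="label")


def _truncated_svd(Xc: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Top-k right singular vectors and singular values of centered data."""
    n, p = Xc.shape
    full_rank = min(n, p)
    if k >= full_rank or full_rank <= 400:
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        return s, vt
    from sklearn.utils.extmath import randomized_svd

    _, s, vt = randomized_svd(
        Xc, n_components=k, n_iter=7, random_state=seed, flip_sign=False
    )
    return s, vt


def fit_pca(X: np.ndarray | pd.DataFrame, tau: float = 0.95) -> PCAModel:
    """Fit centered PCA and apply the cumulative-variance retention rule.

    For wide patch-level matrices a seeded randomized SVD computes only as many
    leading components as the threshold requires; explained-variance ratios are
    always relative to the total variance of ``X``, so ``retained`` is
    identical to what a full decomposition would give.
    """
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise FitError(f"PCA requires a 2D matrix with >= 2 rows, got shape {arr.shape}")
    if not (0 < tau <= 1):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if not np.all(np.isfinite(arr)):
        raise FitError("PCA input contains non-finite values")

    n = arr.shape[0]
    mean = arr.mean(axis=0)
    Xc = arr - mean
    total_var = float((Xc**2).sum()) / (n - 1)
    if total_var == 0:
        raise FitError("PCA input has zero variance")

    full_rank = min(arr.shape)
    k = min(full_rank, 128)
    while True:
        s, vt = _truncated_svd(Xc, k)
        evr = (s**2) / (n - 1) / total_var
        cum = np.cumsum(evr)
        if cum[-1] >= tau - 1e-12 or len(s) >= full_rank:
            break
        k = min(full_rank, 2 * k)

    retained = int(np.searchsorted(cum, tau - 1e-12) + 1)
    retained = min(retained, len(s))

    # sign convention: largest-|entry| of each loading is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]

    return PCAModel(mean=mean, loadings=vt, evr=evr, retained=retained, tau=float(tau))


def transform_pca(model: PCAModel, X: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Project rows onto the retained loadings after centering by the fit mean."""
    index = X.index if isinstance(X, pd.DataFrame) else None
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != model.mean.shape[0]:
        raise SchemaError(
            f"expected {model.mean.shape[0]} feature columns, got shape {arr.shape}"
        )
    scores = (arr - model.mean) @ model.loadings[: model.retained].T
    return pd.DataFrame(scores, index=index, columns=model.component_names)


def subject_pc_scores(
    patches: Sequence[Patch],
    tau: float = 0.95,
    mode: Literal["pca_then_mean", "mean"] = "pca_then_mean",
) -> tuple[pd.DataFrame, pd.Series, PCAModel]:
    """Full patch -> subject PC-score route.

    ``pca_then_mean``: PCA on the patch matrix, then per-subject mean score.
    ``mean``: per-subject mean patch vector, then PCA on the subject matrix.
    Returns (scores indexed by subject_id, labels, fitted PCAModel).
    """
    if mode == "mean":
        feats, labels = aggregate_subject_features(patches, mode="mean")
        model = fit_pca(feats.to_numpy(), tau=tau)
        scores = transform_pca(model, feats)
        return scores, labels, model

    if mode != "pca_then_mean":
        raise ValueError(f"unknown mode {mode!r}")
    X, meta = patches_to_matrix(patches)
    model = fit_pca(X, tau=tau)
    patch_scores = transform_pca(model, X).to_numpy()
    order: list[str] = []
    for sid in meta["subject_id"]:
        if sid not in order:
            order.append(sid)
    rows, labels = [], []
    for sid in order:
        sel = (meta["subject_id"] == sid).to_numpy()
        rows.append(patch_scores[sel].mean(axis=0))
        labels.append(int(meta.loc[sel, "label"].iloc[0]))
    scores = pd.DataFrame(
        np.stack(rows),
        index=pd.Index(order, name="subject_id"),
        columns=model.component_names,
    )
    return scores, pd.Series(labels, index=scores.index, name="label"), model


def save_pca_model(model: PCAModel, path: str) -> None:
    """Serialize to ``path`` (JSON metadata) plus a ``.npz``-free text sidecar."""
    meta = {
        "retained": model.retained,
        "tau": model.tau,
        "evr": model.evr.tolist(),
        "mean_file": os.path.basename(path) + ".mean.txt",
        "loadings_file": os.path.basename(path) + ".loadings.txt",
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)
    d = os.path.dirname(os.path.abspath(path))
    np.savetxt(os.path.join(d, meta["mean_file"]), model.mean)
    np.savetxt(os.path.join(d, meta["loadings_file"]), model.loadings)


def load_pca_model(path: str) -> PCAModel:
    with open(path) as fh:
        meta = json.load(fh)
    d = os.path.dirname(os.path.abspath(path))
    mean = np.loadtxt(os.path.join(d, meta["mean_file"]))
    loadings = np.atleast_2d(np.loadtxt(os.path.join(d, meta["loadings_file"])))
    return PCAModel(
        mean=mean,
        loadings=loadings,
        evr=np.asarray(meta["evr"], dtype=float),
        retained=int(meta["retained"]),
        tau=float(meta["tau"]),
    )
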