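"""Discrimination machinery: scaled PCA on gene sets and LOOCV ROC.

Scaled PCA (center each gene's log2 values and scale to unit variance, then
eigen-decompose -- the ``prcomp(scale = TRUE)`` construction) summarizes a
functional gene set into a few sample scores.  Loadings fitted on one cohort
can be applied to an independent cohort after standardizing that cohort with
its *own* per-gene center and scale, which absorbs cross-platform location
and scale shifts.

The classifier evaluated by leave-one-out cross-validation is deliberately
minimal: a sample's score is its maximum marker-panel fold-change over the
gene set, with the baseline recomputed from the training fold's normal
samples in every fold to avoid information leak.  A PC1-score variant is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ROCReport

log = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Per-gene standardization constants plus orthonormal loadings."""

    genes: list[str]
    center: pd.Series  # log2 space
    scale: pd.Series
    loadings: pd.DataFrame  # genes x components
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    training_scores: pd.DataFrame  # samples x components


def _standardize(log2v: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center and unit-variance scale each gene (rows) of a log2 matrix."""
    center = log2v.mean(axis=1)
    scale = log2v.std(axis=1, ddof=1)
    z = log2v.sub(center, axis=0).div(scale, axis=0)
    return z, center, scale


def pca_fit(expr: ExpressionMatrix, genes: Sequence[str]) -> PCAModel:
    """Scaled PCA of the samples over ``genes``.

    Zero-variance genes are dropped with a logged warning; fewer than two
    usable genes is an error.  The sign convention fixes each loading's
    largest-magnitude element to be positive.
    """
    sub = expr.subset_genes(genes)
    log2v = np.log2(sub.values)
    sd = log2v.std(axis=1, ddof=1)
    usable = sd > 1e-12  # tolerate float jitter in constant rows
    if (~usable).any():
        log.warning("dropping zero-variance genes: %s", list(sd.index[~usable]))
        log2v = log2v.loc[usable]
    if log2v.shape[0] < 2:
        raise ValueError("scaled PCA needs >= 2 genes with non-zero variance")
    if log2v.shape[1] < 3:
        raise ValueError("scaled PCA needs >= 3 samples")

    z, center, scale = _standardize(log2v)
    X = z.to_numpy().T  # samples x genes
    n = X.shape[0]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    eig, vt = eig[keep], vt[keep]
    loadings = vt.T  # genes x components
    # sign convention: largest-|element| of each loading positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAModel(
        genes=list(log2v.index),
        center=center,
        scale=scale,
        loadings=pd.DataFrame(loadings, index=log2v.index, columns=comp_names),
        explained_variance_ratio=eig / eig.sum(),
        eigenvalues=eig,
        training_scores=pd.DataFrame(scores, index=sub.samples, columns=comp_names),
    )


def pca_project(model: PCAModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Project a cohort onto the model's loadings.

    The new cohort is standardized with its *own* per-gene center and scale
    before multiplication by the training loadings, so projecting the
    training matrix reproduces the stored training scores exactly.
    """
    missing = [g for g in model.genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"model genes absent from matrix: {missing}")
    log2v = np.log2(expr.values.loc[model.genes])
    z, _, _ = _standardize(log2v)
    scores = z.to_numpy().T @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=expr.samples, columns=model.loadings.columns)


# ---------------------------------------------------------------------------
# ROC / LOOCV
# ---------------------------------------------------------------------------

def roc_curve_from_scores(scores: np.ndarray, labels: np.ndarray
                          ) -> tuple[pd.DataFrame, float]:
    """ROC over the observed score grid; AUC by trapezoid.

    Ties receive half credit, so the trapezoid AUC equals the pairwise
    concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": sens,
                          "specificity": spec})
    return curve, auc


def loocv_roc(expr: ExpressionMatrix, genes: Sequence[str],
              tumor_labels: pd.Series, score: str = "panel_fc",
              baseline_group: str = "NOR") -> ROCReport:
    """Leave-one-out ROC of the gene-set score against tumor labels.

    ``score='panel_fc'`` (default): the held-out sample's score is its
    maximum fold-change over ``genes`` relative to the *training fold's*
    normal-group mean.  ``score='pc1'``: the held-out sample's first
    principal-component coordinate from a scaled PCA fitted on the training
    fold (training-fold standardization, sign aligned so tumors score high).
    The operating point maximizes Youden's J = sensitivity + specificity - 1.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    labels = tumor_labels.reindex(expr.samples)
    if labels.isna().any():
        raise ValueError("tumor_labels must cover every sample")
    labels = labels.astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")

    values = expr.values.loc[genes]
    nor_samples = expr.samples_in(baseline_group)
    scores = {}
    for held in expr.samples:
        train_nor = [s for s in nor_samples if s != held]
        if not train_nor:
            raise ValueError(f"no {baseline_group} samples left in the training fold")
        if score == "panel_fc":
            base = values[train_nor].mean(axis=1)
            scores[held] = float((values[held] / base).max())
        elif score == "pc1":
            train = [s for s in expr.samples if s != held]
            model = pca_fit(ExpressionMatrix(expr.values[train],
                                             expr.groups[train] if expr.groups is not None else None),
                            genes)
            z = (np.log2(values[held]).loc[model.genes] - model.center) / model.scale
            pc1 = float(z.to_numpy() @ model.loadings.to_numpy()[:, 0])
            train_lab = labels[train]
            sign = np.sign(model.training_scores.loc[train_lab[train_lab].index, "PC1"].mean()
                           - model.training_scores.loc[train_lab[~train_lab].index, "PC1"].mean())
            scores[held] = pc1 * (sign or 1.0)
        else:
            raise ValueError(f"unknown score {score!r}")

    score_arr = np.array([scores[s] for s in expr.samples])
    label_arr = labels.to_numpy()
    curve, auc = roc_curve_from_scores(score_arr, label_arr)
    j = curve["sensitivity"] + curve["specificity"] - 1.0
    best = int(j.idxmax())
    return ROCReport(
        scores=pd.DataFrame({"score": score_arr, "tumor": label_arr},
                            index=expr.samples),
        curve=curve,
        auc=auc,
        sensitivity=float(curve.loc[best, "sensitivity"]),
        specificity=float(curve.loc[best, "specificity"]),
        threshold=float(curve.loc[best, "threshold"]),
    )
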