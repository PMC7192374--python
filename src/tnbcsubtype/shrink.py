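"""Nearest-shrunken-centroids signature reduction.

Given a labeled, log2-centered training cohort, class-mean deviations from the
overall centroid are standardized and soft-thresholded by a shrinkage amount
``delta``; genes whose deviations survive for at least one class form the
reduced signature.  The standard formulation is used: for gene i and class k
with n_k of n samples,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

with s_i the pooled within-class standard deviation, s0 the median of the
s_i (a stabilizer against near-zero variances), and the shrunken deviation
d'_ik = sign(d_ik) * max(|d_ik| - delta, 0).  Shrunken class centroids are
reconstructed as xbar_i + m_k * (s_i + s0) * d'_ik.

The exported reduced :class:`~tnbcsubtype.io.CentroidSet` is consumed by the
Spearman correlation classifier — the signature is derived by shrinkage but
deployed via rank correlation, mirroring how reduced clinical signatures are
built from larger discovery gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CentroidSet, ExpressionMatrix

__all__ = [
    "ShrunkenModel",
    "train_shrunken_centroids",
    "predict_shrunken",
    "choose_delta",
    "export_centroids",
]


@dataclass
class ShrunkenModel:
    """A fitted nearest-shrunken-centroids model.

    ``class_centroids`` holds the SHRUNKEN per-class centroids (equal to the
    raw class means at delta = 0); ``shrunken_deviations`` the soft-thresholded
    standardized deviations d'_ik.
    """

    overall_centroid: pd.Series
    class_centroids: pd.DataFrame
    shrunken_deviations: pd.DataFrame
    delta: float
    per_gene_s: pd.Series
    s0: float
    m_k: pd.Series
    n_per_class: pd.Series

    @property
    def classes(self) -> list[str]:
        return list(self.class_centroids.columns)

    @property
    def selected_genes(self) -> list[str]:
        """Genes with a nonzero shrunken deviation for at least one class."""
        mask = (self.shrunken_deviations != 0).any(axis=1)
        return list(self.shrunken_deviations.index[mask])


def _as_labels(labels, samples: pd.Index) -> pd.Series:
    s = pd.Series(labels)
    if not s.index.equals(samples):
        if len(s) != len(samples):
            raise ValidationError("one label per sample required")
        s.index = samples
    return s.astype(str)


def train_shrunken_centroids(
    matrix: ExpressionMatrix, labels, delta: float
) -> ShrunkenModel:
    """Fit shrunken centroids at shrinkage threshold ``delta``.

    Requires >=2 classes with >=2 samples each; ``delta`` >= 0.  At delta = 0
    the shrunken class centroids equal the raw class means exactly.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    y = _as_labels(labels, matrix.data.columns)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValidationError("need >=2 classes")
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"classes with <2 samples: {list(small.index)}")

    X = matrix.data  # genes x samples
    n = X.shape[1]
    classes = sorted(counts.index)
    overall = X.mean(axis=1)
    class_means = pd.DataFrame(
        {k: X.loc[:, (y == k).to_numpy()].mean(axis=1) for k in classes}
    )
    # pooled within-class variance: sum_k sum_{j in k} (x_ij - xbar_ik)^2 / (n - K)
    ss = pd.Series(0.0, index=X.index)
    for k in classes:
        block = X.loc[:, (y == k).to_numpy()]
        ss += ((block.sub(class_means[k], axis=0)) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(s.median())
    m_k = pd.Series({k: np.sqrt(1.0 / counts[k] - 1.0 / n) for k in classes})

    denom = (s + s0).to_numpy()[:, None] * m_k.to_numpy()[None, :]
    d = (class_means.sub(overall, axis=0)).to_numpy() / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = pd.DataFrame(d_shrunk, index=X.index, columns=classes)
    centroids = pd.DataFrame(
        overall.to_numpy()[:, None] + denom * d_shrunk, index=X.index, columns=classes
    )
    return ShrunkenModel(
        overall_centroid=overall,
        class_centroids=centroids,
        shrunken_deviations=shrunken,
        delta=float(delta),
        per_gene_s=s,
        s0=s0,
        m_k=m_k,
        n_per_class=counts.loc[classes],
    )


def predict_shrunken(model: ShrunkenModel, matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Classify samples by the shrunken-centroid discriminant score.

    Equal class priors: score_k(x) = sum_i (x_i - c_ik)^2 / (s_i + s0)^2,
    minimized over k.  At delta = 0 this is variance-weighted
    nearest-class-mean classification.
    """
    X = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if not X.index.equals(model.class_centroids.index):
        X = X.reindex(model.class_centroids.index)
        if X.isna().to_numpy().any():
            raise ValidationError("prediction matrix is missing training genes")
    w = 1.0 / (model.per_gene_s + model.s0) ** 2
    scores = pd.DataFrame(
        {
            k: ((X.sub(model.class_centroids[k], axis=0) ** 2).mul(w, axis=0)).sum(axis=0)
            for k in model.classes
        }
    )
    return scores.idxmin(axis=1)


def choose_delta(
    matrix: ExpressionMatrix,
    labels,
    delta_grid,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the grid delta minimizing stratified cross-validated error.

    Ties are broken toward the LARGER delta, i.e. the smaller signature.
    Deterministic for a fixed seed.
    """
    from sklearn.model_selection import StratifiedKFold

    grid = sorted(set(float(d) for d in delta_grid))
    if not grid:
        raise ValidationError("delta grid is empty")
    if n_folds < 2:
        raise ValidationError("need >=2 folds")
    y = _as_labels(labels, matrix.data.columns)
    if int(y.value_counts().min()) < n_folds:
        raise ValidationError(
            "stratification impossible: a class has fewer samples than folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    samples = matrix.data.columns
    errors = {d: 0 for d in grid}
    for train_idx, test_idx in skf.split(samples, y):
        train = ExpressionMatrix(
            matrix.data.iloc[:, train_idx], scale=matrix.scale
        )
        test_block = matrix.data.iloc[:, test_idx]
        y_train, y_test = y.iloc[train_idx], y.iloc[test_idx]
        for d in grid:
            model = train_shrunken_centroids(train, y_train, d)
            pred = predict_shrunken(model, test_block)
            errors[d] += int((pred.to_numpy() != y_test.to_numpy()).sum())
    best = min(grid, key=lambda d: (errors[d], -d))
    return best


def export_centroids(model: ShrunkenModel, algorithm_label: str = "") -> CentroidSet:
    """Reduced CentroidSet over the selected genes, directly usable by the
    correlation classifier."""
    genes = model.selected_genes
    if not genes:
        raise ValidationError(
            "no genes survive the shrinkage threshold; lower delta to keep a signature"
        )
    label = algorithm_label or f"{len(genes)}-gene shrunken signature (delta={model.delta:g})"
    return CentroidSet(model.class_centroids.loc[genes].copy(), algorithm_label=label)
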