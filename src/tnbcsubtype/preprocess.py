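"""Log2 transformation and per-gene, per-batch centering.

The classifier consumes log2-transformed, per-gene centered expression.
Centering is done independently within each batch so that an additive
per-gene platform or condition offset (for instance between cell cultures and
xenograft tumors profiled on different pipelines) cancels exactly before
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TnbcSubtypeError, ValidationError
from .io import ExpressionMatrix, Scale

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the expression transform.

    pseudocount
        Added before log2; must be positive when the matrix contains zeros
        (FPKM matrices almost always do).  Default 1.0, i.e. log2(x + 1).
    centering_statistic
        ``"mean"`` (default, the usual convention for centroid classifiers)
        or ``"median"``.
    """

    pseudocount: float = 1.0
    centering_statistic: str = "mean"

    def __post_init__(self):
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.centering_statistic not in ("mean", "median"):
            raise ValidationError(
                f"centering_statistic must be 'mean' or 'median', got {self.centering_statistic!r}"
            )


def log2_transform(matrix: ExpressionMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Map every linear-scale value v to log2(v + pseudocount).

    Strictly monotone per entry, so within-sample gene ranks are preserved —
    the property the downstream rank-based classifier relies on.
    """
    config = config or PreprocessConfig()
    if matrix.scale is not Scale.LINEAR:
        raise ValidationError(f"log2_transform expects a linear-scale matrix, got {matrix.scale.value}")
    values = matrix.data.to_numpy()
    if config.pseudocount == 0 and (values == 0).any():
        raise TnbcSubtypeError("zero expression values need a positive pseudocount")
    return matrix.with_data(np.log2(matrix.data + config.pseudocount), Scale.LOG2)


def center_genes(
    matrix: ExpressionMatrix,
    batch_labels: pd.Series | None = None,
    config: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Subtract each gene's centering statistic within each batch.

    With no batch labels (neither given here nor carried by the matrix) the
    whole matrix is treated as one batch.  A single-sample batch centers to an
    all-zero, uninformative profile; this is permitted with a logged warning
    because small xenograft sets are a legitimate use, and such a profile will
    classify as UNS downstream.
    """
    config = config or PreprocessConfig()
    if matrix.scale is not Scale.LOG2:
        raise ValidationError(f"center_genes expects a log2 matrix, got {matrix.scale.value}")
    if batch_labels is None:
        batch_labels = matrix.batch
    if batch_labels is None:
        batch_labels = pd.Series("batch0", index=matrix.data.columns)
    else:
        batch_labels = pd.Series(batch_labels)
        unknown = [s for s in batch_labels.index if s not in matrix.data.columns]
        if unknown:
            raise ValidationError(f"batch labels for unknown samples: {unknown}")
        batch_labels = batch_labels.reindex(matrix.data.columns)
        if batch_labels.isna().any():
            missing = list(batch_labels.index[batch_labels.isna()])
            raise ValidationError(f"samples without a batch label: {missing}")

    centered = matrix.data.copy()
    for batch, cols in matrix.data.columns.to_series().groupby(batch_labels, sort=False):
        block = matrix.data[list(cols)]
        if block.shape[1] == 1:
            log.warning(
                "batch %r has a single sample; centering makes it uninformative "
                "(it will classify as UNS)", batch,
            )
        # statistic computed on per-gene SORTED values: bit-identical under any
        # permutation of samples, so equal values stay exactly tied after centering
        ordered = np.sort(block.to_numpy(), axis=1)
        if config.centering_statistic == "mean":
            stat = ordered.mean(axis=1)
        else:
            stat = np.median(ordered, axis=1)
        centered[list(cols)] = block.sub(pd.Series(stat, index=block.index), axis=0)
    out = ExpressionMatrix(centered, scale=Scale.LOG2_CENTERED, batch=matrix.batch)
    out.batch = batch_labels
    return out


def preprocess(
    matrix: ExpressionMatrix,
    batch_labels: pd.Series | None = None,
    config: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Bring a matrix of any declared scale to the log2-centered scale."""
    config = config or PreprocessConfig()
    if matrix.scale is Scale.LINEAR:
        matrix = log2_transform(matrix, config)
    if matrix.scale is Scale.LOG2:
        matrix = center_genes(matrix, batch_labels, config)
    return matrix
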