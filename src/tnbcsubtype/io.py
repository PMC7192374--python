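"""Expression matrices, centroid tables and signature-coverage checks.

The on-disk convention follows typical FPKM exports: genes in rows (first
column = gene identifiers), samples in columns (header row = sample
identifiers).  Centroid tables use the same layout with subtype names as
columns; an optional final ``IM`` column carries the immunomodulatory overlay
centroid.  Gene identifiers are matched as exact, case-sensitive strings —
no symbol/alias translation is attempted.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Column name that marks the immunomodulatory overlay centroid in a table.
IM_COLUMN = "IM"

_WRITE_FLOAT_FORMAT = "%.6g"


class Scale(str, Enum):
    """Scale of the values in an :class:`ExpressionMatrix`.

    ``linear``
        FPKM/RPKM or array intensities; all values non-negative.
    ``log2``
        log2-transformed values, not yet gene-centered.
    ``log2_centered``
        log2-transformed and per-gene centered within batch; the
        representation the classifier consumes.
    """

    LINEAR = "linear"
    LOG2 = "log2"
    LOG2_CENTERED = "log2_centered"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with scale and batch metadata.

    Parameters
    ----------
    data
        DataFrame with unique gene identifiers as index and unique sample
        identifiers as columns.
    scale
        Scale of the values (see :class:`Scale`).
    batch
        Optional per-sample batch labels (index must equal the sample ids);
        per-gene centering is done within each batch.
    """

    data: pd.DataFrame
    scale: Scale = Scale.LINEAR
    batch: pd.Series | None = None

    def __post_init__(self):
        self.scale = Scale(self.scale)
        idx, cols = self.data.index, self.data.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValidationError("expression matrix must have >=1 gene and >=1 sample")
        for label, ids in (("gene", idx), ("sample", cols)):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {label} identifier(s): {sorted(set(dup))}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if self.scale is Scale.LINEAR and values.min() < 0:
            raise ValidationError("linear-scale expression values must be >= 0")
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            if not self.batch.index.equals(cols):
                self.batch = self.batch.reindex(cols)
                if self.batch.isna().any():
                    missing = list(self.batch.index[self.batch.isna()])
                    raise ValidationError(f"samples without a batch label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale: Scale) -> "ExpressionMatrix":
        """Copy of this matrix with new values/scale, keeping batch labels."""
        return ExpressionMatrix(data, scale=scale, batch=self.batch)


@dataclass
class CentroidSet:
    """Per-gene reference profiles, one column per subtype.

    ``im_centroid`` is an optional overlay profile over the same genes used to
    score IM (immunomodulatory) status independently of the subtype.
    """

    data: pd.DataFrame
    im_centroid: pd.Series | None = None
    algorithm_label: str = ""

    def __post_init__(self):
        idx, cols = self.data.index, self.data.columns
        if len(cols) < 2:
            raise ValidationError("a centroid set needs >=2 subtypes")
        if idx.duplicated().any():
            raise ValidationError("duplicate gene identifiers in centroid set")
        if cols.duplicated().any():
            raise ValidationError("duplicate subtype names in centroid set")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValidationError("centroid values must be finite")
        if self.im_centroid is not None:
            self.im_centroid = pd.Series(self.im_centroid)
            if not self.im_centroid.index.equals(idx):
                raise ValidationError("IM centroid must cover exactly the centroid genes")
            if not np.all(np.isfinite(self.im_centroid.to_numpy())):
                raise ValidationError("IM centroid values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of a centroid signature absent from an expression matrix."""

    n_signature_genes: int
    n_present: int
    missing_gene_ids: list[str] = field(default_factory=list)
    max_missing: float = 0.10

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_present / self.n_signature_genes

    @property
    def ok(self) -> bool:
        """True unless the missing fraction STRICTLY exceeds the allowance."""
        return self.missing_fraction <= self.max_missing


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    try:
        raw = pd.read_csv(_io.StringIO(text), sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (wrong delimiter?)")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, column {col!r}"
        )
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row for gene {gene!r}")
    numeric.index = numeric.index.astype(str)
    numeric.index.name = raw.index.name
    return numeric


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    scale: Scale | str = Scale.LINEAR,
    batch: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample expression table.

    The first column holds gene identifiers and the header row sample
    identifiers.  ``delimiter`` defaults to ``','`` for ``.csv`` files and tab
    otherwise.  ``scale`` declares the scale of the stored values; it is not
    inferred.
    """
    data = _read_table(path, delimiter)
    dup = data.index[data.index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene identifier(s): {sorted(set(dup))}")
    return ExpressionMatrix(data, scale=Scale(scale), batch=batch)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix in the same layout :func:`read_expression_matrix` reads."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    out = matrix.data.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep=sep, float_format=_WRITE_FLOAT_FORMAT)


def read_centroids(
    path: str | Path, delimiter: str | None = None, algorithm_label: str = ""
) -> CentroidSet:
    """Read a centroid table; a final ``IM`` column becomes the IM centroid."""
    data = _read_table(path, delimiter)
    if data.index.duplicated().any():
        raise ValidationError("duplicate gene identifier(s) in centroid table")
    im = None
    if IM_COLUMN in data.columns:
        im = data[IM_COLUMN]
        data = data.drop(columns=[IM_COLUMN])
    return CentroidSet(data, im_centroid=im, algorithm_label=algorithm_label)


def write_centroids(centroids: CentroidSet, path: str | Path, delimiter: str | None = None) -> None:
    out = centroids.data.copy()
    if centroids.im_centroid is not None:
        out[IM_COLUMN] = centroids.im_centroid
    out.index.name = out.index.name or "gene"
    out.to_csv(Path(path), sep=_infer_delimiter(Path(path), delimiter), float_format=_WRITE_FLOAT_FORMAT)


def sum_transcript_fpkm(transcript_table: pd.DataFrame, scale: Scale | str = Scale.LINEAR) -> ExpressionMatrix:
    """Collapse a transcript-level FPKM table to gene level by summation.

    ``transcript_table`` must have columns ``gene_id`` and ``transcript_id``
    followed by one numeric column per sample.  Each gene's value per sample is
    the sum of its transcripts' FPKM.  Output genes are sorted
    lexicographically, so the result is invariant to transcript row order.
    """
    for col in ("gene_id", "transcript_id"):
        if col not in transcript_table.columns:
            raise ValidationError(f"transcript table needs a {col!r} column")
    values = transcript_table.drop(columns=["gene_id", "transcript_id"])
    if values.shape[1] == 0:
        raise ValidationError("transcript table has no sample columns")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)):
        raise ValidationError("FPKM values must be finite numbers")
    if arr.min() < 0:
        raise ValidationError("FPKM values must be >= 0")
    summed = values.groupby(transcript_table["gene_id"].astype(str)).sum().sort_index()
    summed.index.name = "gene"
    return ExpressionMatrix(summed, scale=Scale(scale))


def check_gene_coverage(
    matrix: ExpressionMatrix | Sequence[str],
    centroids: CentroidSet,
    max_missing: float = 0.10,
) -> CoverageReport:
    """Report which signature (centroid) genes are absent from a matrix.

    Classification must be refused when the missing fraction strictly exceeds
    ``max_missing`` (default 10%); a fraction exactly at the limit passes.
    The report is invariant to gene order in either input.
    """
    if not 0 <= max_missing <= 1:
        raise ValidationError(f"max_missing must be in [0, 1], got {max_missing}")
    signature = centroids.gene_ids
    if not signature:
        raise ValidationError("centroid set has no genes")
    present = set(matrix.gene_ids if isinstance(matrix, ExpressionMatrix) else matrix)
    missing = sorted(g for g in signature if g not in present)
    return CoverageReport(
        n_signature_genes=len(signature),
        n_present=len(signature) - len(missing),
        missing_gene_ids=missing,
        max_missing=max_missing,
    )
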