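"""Per-sample subtype call records and their TSV serialization.

A call records the outcome of the correlation-based decision procedure for one
sample: a single predominant subtype, a ranked dual subtype, or UNS (unstable,
no centroid correlation above the cutoff), plus the IM (immunomodulatory)
overlay status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError

#: Label used on disk and in reports for unstable (no-subtype) calls.
UNS = "UNS"

#: Number of significant digits used when serializing correlation values.
FLOAT_DIGITS = 6


class CallStatus(str, Enum):
    SINGLE = "single"
    DUAL = "dual"
    UNSTABLE = "unstable"


class IMStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CorrelationVector:
    """Spearman correlations of one sample profile against every subtype centroid.

    Parameters
    ----------
    rho
        Mapping subtype name -> Spearman rho in [-1, 1] (NaN when the sample
        profile had zero variance over the shared genes).
    n_genes_used
        Number of genes common to the sample and the centroid set, i.e. the
        sample size of each correlation.
    """

    rho: dict[str, float]
    n_genes_used: int

    def __post_init__(self):
        if self.n_genes_used < 3:
            raise ValidationError(
                f"correlation needs at least 3 shared genes, got {self.n_genes_used}"
            )
        for name, r in self.rho.items():
            if not math.isnan(r) and not -1.0 <= r <= 1.0:
                raise ValidationError(f"rho for {name!r} out of [-1, 1]: {r}")

    @property
    def subtypes(self) -> list[str]:
        return list(self.rho)


@dataclass
class SubtypeCall:
    """Decision record for one sample.

    ``dual_subtypes`` is the full ranked list (including the primary) when
    ``status`` is dual, empty otherwise.  ``candidates_above_cutoff`` lists all
    subtypes whose correlation strictly exceeded the cutoff, ranked by
    decreasing correlation.
    """

    sample_id: str
    status: CallStatus
    primary_subtype: str | None
    primary_rho: float
    dual_subtypes: list[tuple[str, float]] = field(default_factory=list)
    candidates_above_cutoff: list[str] = field(default_factory=list)
    im_status: IMStatus = IMStatus.UNDETERMINED
    correlations: CorrelationVector | None = None

    def __post_init__(self):
        if self.status is CallStatus.UNSTABLE:
            if self.primary_subtype is not None or self.candidates_above_cutoff:
                raise ValidationError(
                    f"{self.sample_id}: unstable call cannot carry a subtype"
                )
        else:
            if self.primary_subtype is None:
                raise ValidationError(
                    f"{self.sample_id}: non-UNS call needs a primary subtype"
                )
        if self.status is CallStatus.DUAL:
            if len(self.dual_subtypes) < 2:
                raise ValidationError(
                    f"{self.sample_id}: dual call needs >=2 ranked subtypes"
                )
            rhos = [r for _, r in self.dual_subtypes]
            if any(b > a for a, b in zip(rhos, rhos[1:])):
                raise ValidationError(
                    f"{self.sample_id}: dual subtypes must be ranked by decreasing rho"
                )

    @property
    def label(self) -> str:
        """Primary subtype name, or ``"UNS"`` for unstable calls."""
        return self.primary_subtype if self.primary_subtype is not None else UNS


def _fmt(x: float) -> str:
    return f"{x:.{FLOAT_DIGITS}g}"


def _fmt_pairs(pairs: Iterable[tuple[str, float]]) -> str:
    return ";".join(f"{name}:{_fmt(r)}" for name, r in pairs)


def _parse_pairs(text: str) -> list[tuple[str, float]]:
    if not text:
        return []
    out = []
    for token in text.split(";"):
        name, _, value = token.rpartition(":")
        if not name:
            raise ParseError(f"malformed name:rho token {token!r}")
        out.append((name, float(value)))
    return out


_CALL_COLUMNS = [
    "sample",
    "status",
    "primary_subtype",
    "primary_rho",
    "dual_subtypes",
    "candidates",
    "im_status",
    "correlations",
    "n_genes_used",
]


def write_calls(calls: Sequence[SubtypeCall], path: str | Path) -> None:
    """Write subtype calls as a one-header TSV.

    Dual subtypes and the full correlation vector are serialized as
    semicolon-joined ``name:rho`` pairs; floats are written with 6 significant
    digits.  The table round-trips through :func:`read_calls`.
    """
    if not calls:
        raise ValidationError("refusing to write an empty call table")
    lines = ["\t".join(_CALL_COLUMNS)]
    for c in calls:
        corr = c.correlations
        lines.append(
            "\t".join(
                [
                    c.sample_id,
                    c.status.value,
                    c.label,
                    _fmt(c.primary_rho) if not math.isnan(c.primary_rho) else "nan",
                    _fmt_pairs(c.dual_subtypes),
                    ";".join(c.candidates_above_cutoff),
                    c.im_status.value,
                    _fmt_pairs(corr.rho.items()) if corr is not None else "",
                    str(corr.n_genes_used) if corr is not None else "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calls(path: str | Path) -> list[SubtypeCall]:
    """Read a call table written by :func:`write_calls`."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty call table")
    header = lines[0].split("\t")
    if header != _CALL_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header!r}")
    calls = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(_CALL_COLUMNS):
            raise ParseError(f"{path}: row has {len(f)} fields, expected {len(_CALL_COLUMNS)}")
        corr = None
        if f[7]:
            corr = CorrelationVector(dict(_parse_pairs(f[7])), int(f[8]))
        status = CallStatus(f[1])
        calls.append(
            SubtypeCall(
                sample_id=f[0],
                status=status,
                primary_subtype=None if f[2] == UNS else f[2],
                primary_rho=float(f[3]),
                dual_subtypes=_parse_pairs(f[4]),
                candidates_above_cutoff=f[5].split(";") if f[5] else [],
                im_status=IMStatus(f[6]),
                correlations=corr,
            )
        )
    return calls
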