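"""Packaged reference call tables.

Two small TSV tables of published subtype calls are shipped with the package:

* ``tnbc17_panel``: 17 TNBC cell lines called in vitro and as xenografts by
  the 2188-gene classifier and by the reduced 101-gene classifier with IM
  overlay — the desk-scale input for cross-algorithm and cross-condition
  concordance analysis.
* ``stable6_multisource``: the six molecularly stable lines re-called from
  five independent expression sources.

Cells are compact ``SUBTYPE(rho)`` strings with an optional ranked dual
partner; only the reported correlations are available (the full per-subtype
correlation vectors would require the original expression data and centroid
tables), so loaded calls carry ``correlations=None``.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

from .calls import CallStatus, IMStatus, SubtypeCall, UNS
from .errors import ParseError

_CELL_RE = re.compile(r"^(?P<name>[A-Za-z0-9]+)\((?P<rho>-?[0-9.]+)\)$")

#: Marker for "cell line not represented in this dataset".
ABSENT = "*"


def parse_call_cell(sample_id: str, text: str) -> SubtypeCall | None:
    """Parse one ``SUBTYPE(rho)[;dual:SUBTYPE(rho)]`` cell; None for absent."""
    text = text.strip()
    if text == ABSENT or not text:
        return None
    if text == UNS:
        return SubtypeCall(
            sample_id=sample_id,
            status=CallStatus.UNSTABLE,
            primary_subtype=None,
            primary_rho=float("nan"),
        )
    primary, *rest = text.split(";")
    m = _CELL_RE.match(primary.strip())
    if not m:
        raise ParseError(f"cannot parse call cell {text!r} for {sample_id}")
    name, rho = m.group("name"), float(m.group("rho"))
    duals = [(name, rho)]
    for token in rest:
        token = token.strip()
        if not token.startswith("dual:"):
            raise ParseError(f"cannot parse dual annotation {token!r} for {sample_id}")
        dm = _CELL_RE.match(token[len("dual:"):])
        if not dm:
            raise ParseError(f"cannot parse dual annotation {token!r} for {sample_id}")
        duals.append((dm.group("name"), float(dm.group("rho"))))
    if len(duals) == 1:
        return SubtypeCall(
            sample_id=sample_id,
            status=CallStatus.SINGLE,
            primary_subtype=name,
            primary_rho=rho,
            candidates_above_cutoff=[name],
            im_status=IMStatus.UNDETERMINED,
        )
    return SubtypeCall(
        sample_id=sample_id,
        status=CallStatus.DUAL,
        primary_subtype=name,
        primary_rho=rho,
        dual_subtypes=duals,
        candidates_above_cutoff=[n for n, _ in duals],
        im_status=IMStatus.UNDETERMINED,
    )


def _load_wide_calls(filename: str) -> dict[str, list[SubtypeCall]]:
    path = resources.files("tnbcsubtype.data").joinpath(filename)
    lines = [
        ln for ln in Path(str(path)).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    conditions: dict[str, list[SubtypeCall]] = {col: [] for col in header[1:]}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{filename}: ragged row {fields[0]!r}")
        sample = fields[0]
        for col, cell in zip(header[1:], fields[1:]):
            call = parse_call_cell(sample, cell)
            if call is not None:
                conditions[col].append(call)
    return conditions


def load_tnbc17_panel() -> dict[str, list[SubtypeCall]]:
    """Calls for the 17-cell-line panel.

    Keys: ``tnbctype_invitro``, ``tnbctype_im_invitro``, ``tnbctype_xenograft``,
    ``tnbctype_im_xenograft``.
    """
    return _load_wide_calls("tnbc17_panel_calls.tsv")


def load_stable6_multisource() -> dict[str, list[SubtypeCall]]:
    """Calls for the six stable lines across five expression sources.

    Keys: ``gse15361``, ``gse10890``, ``ccle``, ``xenograft``,
    ``tnbctype_2188``.  Cell lines absent from a source are simply missing
    from that condition's list.
    """
    return _load_wide_calls("stable6_multisource_calls.tsv")
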