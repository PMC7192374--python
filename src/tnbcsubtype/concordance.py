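"""Concordance and stability of subtype calls across classifiers and conditions.

A sample pair "matches" under the default rule when both calls carry the same
non-UNS primary subtype — concordance is judged on the highest-correlation
subtype, with dual partners kept as an audit trail.  UNS never matches
anything, including another UNS.  A sample is "stable" across conditions when
every condition where it was measured assigns it the same non-UNS primary
subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .calls import CallStatus, SubtypeCall, UNS
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class SubtypeAgreement:
    """Agreement for samples whose reference call is one particular subtype."""

    n_reference: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_reference


@dataclass
class ConcordanceReport:
    """Pairwise agreement between two call sets over a common sample set.

    The sample space partitions exactly into matched pairs, mismatched
    (both non-UNS, different primary) pairs, and UNS-involving pairs.
    ``per_subtype`` groups agreement by the REFERENCE (first) call set's
    subtype and is therefore direction-dependent; the overall match count is
    symmetric.
    """

    n_samples: int
    n_matched: int
    per_subtype: dict[str, SubtypeAgreement]
    mismatches: list[tuple[str, str, str]] = field(default_factory=list)
    uns_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    dual_count_a: int = 0
    dual_count_b: int = 0
    uns_count_a: int = 0
    uns_count_b: int = 0

    @property
    def match_fraction(self) -> float:
        return self.n_matched / self.n_samples


def _index(calls: Sequence[SubtypeCall]) -> dict[str, SubtypeCall]:
    out = {}
    for c in calls:
        if c.sample_id in out:
            raise ValidationError(f"duplicate sample {c.sample_id!r} in call set")
        out[c.sample_id] = c
    return out


def _pair_matches(a: SubtypeCall, b: SubtypeCall, match_rule: str) -> bool:
    if a.label == UNS or b.label == UNS:
        return False
    if a.label == b.label:
        return True
    if match_rule == "lenient":
        duals_a = {name for name, _ in a.dual_subtypes}
        duals_b = {name for name, _ in b.dual_subtypes}
        return b.label in duals_a or a.label in duals_b
    return False


def concordance_table(
    calls_a: Sequence[SubtypeCall],
    calls_b: Sequence[SubtypeCall],
    match_rule: str = "primary",
) -> ConcordanceReport:
    """Pairwise agreement of two call sets.

    ``match_rule="primary"`` (default) matches on equal non-UNS primary
    subtypes; ``"lenient"`` additionally counts a match when either call's
    dual list contains the other's primary.  Unequal sample sets are reduced
    to their intersection with a warning; an empty intersection is an error.
    """
    if match_rule not in ("primary", "lenient"):
        raise ValidationError(f"unknown match rule {match_rule!r}")
    by_a, by_b = _index(calls_a), _index(calls_b)
    common = [s for s in by_a if s in by_b]
    if not common:
        raise ValidationError("no samples in common between the two call sets")
    if len(common) != len(by_a) or len(common) != len(by_b):
        log.warning(
            "call sets differ (%d vs %d samples); using the %d-sample intersection",
            len(by_a), len(by_b), len(common),
        )
    matched, mismatches, uns_pairs = 0, [], []
    per_subtype: dict[str, SubtypeAgreement] = {}
    for s in common:
        a, b = by_a[s], by_b[s]
        if a.label != UNS:
            agg = per_subtype.setdefault(a.label, SubtypeAgreement(0, 0))
            agg.n_reference += 1
        if _pair_matches(a, b, match_rule):
            matched += 1
            per_subtype[a.label].n_matched += 1
        elif a.label == UNS or b.label == UNS:
            uns_pairs.append((s, a.label, b.label))
        else:
            mismatches.append((s, a.label, b.label))
    return ConcordanceReport(
        n_samples=len(common),
        n_matched=matched,
        per_subtype=per_subtype,
        mismatches=mismatches,
        uns_pairs=uns_pairs,
        dual_count_a=sum(by_a[s].status is CallStatus.DUAL for s in common),
        dual_count_b=sum(by_b[s].status is CallStatus.DUAL for s in common),
        uns_count_a=sum(by_a[s].label == UNS for s in common),
        uns_count_b=sum(by_b[s].label == UNS for s in common),
    )


@dataclass
class StabilityResult:
    """Samples whose primary subtype is identical and non-UNS in every
    condition where they were measured."""

    sample_ids_stable: list[str]
    n_conditions: int
    condition_labels: list[str]
    patterns: dict[str, list[str | None]]  # sample -> per-condition label (None = absent)


def stable_set(call_sets: Sequence[tuple[str, Sequence[SubtypeCall]]]) -> StabilityResult:
    """Identify samples stable across >=2 conditions.

    A sample absent from a condition's call set is skipped for that condition
    rather than breaking stability (it simply was not measured there).  UNS in
    any measured condition, or any disagreement between measured conditions,
    makes a sample unstable.  Output is sorted by sample id.
    """
    if len(call_sets) < 2:
        raise ValidationError("stability needs >=2 conditions")
    labels = [lab for lab, _ in call_sets]
    indexed = [(lab, _index(calls)) for lab, calls in call_sets]
    universe = sorted({s for _, by in indexed for s in by})
    if not universe:
        raise ValidationError("no samples in any condition")
    patterns: dict[str, list[str | None]] = {}
    stable = []
    for s in universe:
        row = [by[s].label if s in by else None for _, by in indexed]
        patterns[s] = row
        observed = [lab for lab in row if lab is not None]
        if observed and UNS not in observed and len(set(observed)) == 1:
            stable.append(s)
    return StabilityResult(
        sample_ids_stable=stable,
        n_conditions=len(call_sets),
        condition_labels=labels,
        patterns=patterns,
    )


def dual_subtype_audit(
    calls: Sequence[SubtypeCall],
) -> tuple[int, list[tuple[str, list[tuple[str, float]]]]]:
    """Count dual-subtype calls and list their ranked subtype pairs."""
    duals = [
        (c.sample_id, list(c.dual_subtypes))
        for c in calls
        if c.status is CallStatus.DUAL
    ]
    return len(duals), duals
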