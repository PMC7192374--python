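"""Spearman-correlation nearest-centroid subtype calling.

Each centered log2 sample profile is correlated (Spearman's rank order, which
tolerates monotone but non-linear relationships between platforms) against a
per-subtype centroid.  The decision procedure:

* candidates are subtypes whose correlation STRICTLY exceeds the cutoff
  (default 0.1);
* no candidate -> UNS (unstable, no subtype assigned);
* one candidate -> that subtype;
* several candidates -> the top candidate is compared with each other
  candidate by a z test on the Fisher-transformed correlations; if every
  other candidate is significantly lower the sample gets the predominant
  subtype alone, otherwise the non-significant candidates are reported with
  it as a dual subtype, ranked by correlation.

IM (immunomodulatory) status is an overlay, scored against its own centroid
with its own cutoff, never a subtype.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls import CallStatus, CorrelationVector, IMStatus, SubtypeCall
from .errors import CoverageError, ValidationError
from .io import CentroidSet, CoverageReport, ExpressionMatrix, Scale, check_gene_coverage
from .preprocess import PreprocessConfig, preprocess

log = logging.getLogger(__name__)

#: |rho| is clipped to this before the Fisher transform (atanh(1) diverges).
RHO_CLIP = 1.0 - 1e-7

#: Variance inflation of Fisher-transformed Spearman (vs Pearson) correlations.
SPEARMAN_VARIANCE_FACTOR = 1.06


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision-procedure parameters.

    cutoff
        Minimum correlation a subtype must strictly exceed to be a candidate
        (default 0.1, shared between the full and reduced signatures).
    alpha
        Two-sided significance level for the candidate-difference z test
        (default 0.05).
    tie_test
        ``"fisher_z"`` (default): independent-correlation z test with the
        Spearman variance adjustment.  ``"steiger"``: dependent-correlation
        variant accounting for the two correlations sharing the same sample.
    im_cutoff
        Cutoff for the IM overlay correlation (default 0.1).
    """

    cutoff: float = 0.1
    alpha: float = 0.05
    tie_test: str = "fisher_z"
    im_cutoff: float = 0.1

    def __post_init__(self):
        if not -1 < self.cutoff < 1:
            raise ValidationError("cutoff must be in (-1, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tie_test not in ("fisher_z", "steiger"):
            raise ValidationError(f"unknown tie_test {self.tie_test!r}")


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_to_centroids(
    sample_profile: pd.Series, centroids: CentroidSet
) -> CorrelationVector:
    """Spearman rho of one centered log2 profile against every subtype centroid.

    Correlations are computed over the gene intersection only, with average
    ranks for ties; ``n_genes_used`` records the intersection size.  A
    zero-variance profile has no defined rank correlation: all rhos are
    returned as NaN (treated downstream as below any cutoff) with a warning.
    """
    shared = centroids.data.index.intersection(sample_profile.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} genes shared between sample and centroids (>=3 required)"
        )
    x = sample_profile.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        log.warning(
            "sample profile has zero variance over the %d signature genes; "
            "correlations undefined, sample will be called UNS", len(shared),
        )
        rho = {name: float("nan") for name in centroids.subtype_names}
        return CorrelationVector(rho, n_genes_used=len(shared))
    rho = {
        name: _spearman(x, centroids.data.loc[shared, name].to_numpy(dtype=float))
        for name in centroids.subtype_names
    }
    return CorrelationVector(rho, n_genes_used=len(shared))


def compare_correlations(
    rho_a: float,
    rho_b: float,
    n_genes: int,
    config: ClassifierConfig | None = None,
    rho_centroids: float = 0.0,
) -> tuple[float, bool]:
    """z test for the difference between two Spearman correlations.

    Default (``fisher_z``): z = (atanh(rho_a) - atanh(rho_b)) /
    sqrt(2 * 1.06 / (n - 3)), where 1.06/(n-3) is the Fieller-adjusted
    variance of a Fisher-transformed Spearman correlation.  ``steiger``
    accounts for the two correlations sharing the sample via the correlation
    between the two centroid profiles (``rho_centroids``; 0 when unknown).

    Returns ``(z, significant)`` with significance two-sided at
    ``config.alpha``.  |rho| = 1 is clipped to 1 - 1e-7 before atanh.
    """
    config = config or ClassifierConfig()
    if n_genes < 4:
        raise ValidationError("the z test needs n_genes >= 4 (variance uses n - 3)")
    clipped = False
    ra, rb = rho_a, rho_b
    if abs(ra) >= 1.0:
        ra, clipped = math.copysign(RHO_CLIP, ra), True
    if abs(rb) >= 1.0:
        rb, clipped = math.copysign(RHO_CLIP, rb), True
    if clipped:
        log.debug("|rho| >= 1 clipped to 1 - 1e-7 before Fisher transform")
    diff = math.atanh(ra) - math.atanh(rb)
    if config.tie_test == "fisher_z":
        se = math.sqrt(2.0 * SPEARMAN_VARIANCE_FACTOR / (n_genes - 3))
    else:  # steiger: dependent correlations sharing the sample profile
        rbar2 = ((ra + rb) / 2.0) ** 2
        cov = (
            rho_centroids * (1.0 - 2.0 * rbar2)
            - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - rho_centroids**2)
        ) / (1.0 - rbar2) ** 2
        se = math.sqrt(max(2.0 - 2.0 * cov, 1e-12) / (n_genes - 3))
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, bool(p < config.alpha)


def call_subtype(
    correlations: CorrelationVector,
    config: ClassifierConfig | None = None,
    sample_id: str = "",
    im_status: IMStatus = IMStatus.UNDETERMINED,
) -> SubtypeCall:
    """Apply the decision tree to one sample's correlation vector.

    Exactly one of {single, dual, unstable} results for any input.  Exact rho
    ties are ordered alphabetically for determinism (a zero difference is
    never significant, so tied tops always end up dual).
    """
    config = config or ClassifierConfig()
    # NaN rho (zero-variance profile) never exceeds the cutoff
    ranked = sorted(
        ((name, r) for name, r in correlations.rho.items() if r > config.cutoff),
        key=lambda item: (-item[1], item[0]),
    )
    candidates = [name for name, _ in ranked]
    if not ranked:
        return SubtypeCall(
            sample_id=sample_id,
            status=CallStatus.UNSTABLE,
            primary_subtype=None,
            primary_rho=float("nan"),
            im_status=im_status,
            correlations=correlations,
        )
    top_name, top_rho = ranked[0]
    dual: list[tuple[str, float]] = [ranked[0]]
    for name, r in ranked[1:]:
        _, significant = compare_correlations(
            top_rho, r, correlations.n_genes_used, config
        )
        if not significant:
            dual.append((name, r))
    if len(dual) == 1:
        status, dual = CallStatus.SINGLE, []
    else:
        status = CallStatus.DUAL
    return SubtypeCall(
        sample_id=sample_id,
        status=status,
        primary_subtype=top_name,
        primary_rho=top_rho,
        dual_subtypes=dual,
        candidates_above_cutoff=candidates,
        im_status=im_status,
        correlations=correlations,
    )


def assess_im_status(
    sample_profile: pd.Series,
    centroids: CentroidSet,
    config: ClassifierConfig | None = None,
) -> IMStatus:
    """Score the IM overlay: positive iff rho against the IM centroid exceeds
    the IM cutoff; undetermined when the centroid set carries no IM profile."""
    config = config or ClassifierConfig()
    if centroids.im_centroid is None:
        return IMStatus.UNDETERMINED
    shared = centroids.data.index.intersection(sample_profile.index)
    if len(shared) < 3:
        raise ValidationError("IM scoring needs >=3 shared genes")
    x = sample_profile.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        log.warning("zero-variance profile: IM correlation undefined, scored negative")
        return IMStatus.NEGATIVE
    rho = _spearman(x, centroids.im_centroid.loc[shared].to_numpy(dtype=float))
    return IMStatus.POSITIVE if rho > config.im_cutoff else IMStatus.NEGATIVE


def classify_cohort(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    pre_config: PreprocessConfig | None = None,
    cls_config: ClassifierConfig | None = None,
    max_missing: float = 0.10,
) -> list[SubtypeCall]:
    """Coverage gate -> preprocessing -> correlation -> call -> IM, per sample.

    Raises :class:`CoverageError` (with the report attached) when more than
    ``max_missing`` of the signature genes are absent.  Signature genes absent
    below that gate are dropped from the correlations, never imputed;
    ``n_genes_used`` in each call records the reduction.  Deterministic given
    inputs and configs.
    """
    report: CoverageReport = check_gene_coverage(matrix, centroids, max_missing)
    if not report.ok:
        raise CoverageError(report, max_missing)
    if report.missing_gene_ids:
        log.warning(
            "%d/%d signature genes absent (%.1f%%); correlations use the remainder",
            len(report.missing_gene_ids), report.n_signature_genes,
            100 * report.missing_fraction,
        )
    processed = (
        matrix if matrix.scale is Scale.LOG2_CENTERED else preprocess(matrix, config=pre_config)
    )
    cls_config = cls_config or ClassifierConfig()
    calls = []
    for sample in processed.sample_ids:
        profile = processed.data[sample]
        corr = correlate_to_centroids(profile, centroids)
        im = assess_im_status(profile, centroids, cls_config)
        calls.append(call_subtype(corr, cls_config, sample_id=sample, im_status=im))
    return calls
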