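"""Synthetic bulk-expression cohorts with planted subtype structure.

The generator emulates the statistical skeleton the subtyping analysis
assumes: K subtype centroids with disjoint blocks of informative genes,
samples drawn around one centroid (single), around a weighted mixture of two
centroids (dual), or around no centroid at all (unstable); an IM
(immunomodulatory) overlay on its own gene block, independent of subtype; and
an additive per-gene condition shift emulating the platform/microenvironment
offset between an in vitro culture and its xenograft tumor.  Noise is
Gaussian on the log2 scale and the emitted matrix is exponentiated to an
FPKM-like linear scale so the full pipeline, including the log2 transform, is
exercised.

Randomness is hierarchical: one root seed spawns an independent stream per
sample (and per purpose), so enlarging a cohort does not reshuffle draws for
earlier samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CentroidSet, ExpressionMatrix, Scale

log = logging.getLogger(__name__)

DEFAULT_SUBTYPES = ("BL1", "BL2", "M", "LAR", "MSL")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a simulated cohort.

    All effect sizes are in log2 units.  ``dual_fraction`` and
    ``unstable_fraction`` are fractions of the whole cohort; the remainder are
    single-subtype samples spread evenly over the subtypes.  ``seed`` is
    mandatory — there is no silent entropy.
    """

    seed: int
    n_genes: int = 500
    subtype_names: tuple[str, ...] = DEFAULT_SUBTYPES
    n_informative_per_subtype: int = 20
    separation: float = 2.0
    noise_sd: float = 1.0
    n_per_subtype: int = 20
    dual_fraction: float = 0.1
    dual_mixing: float = 0.5
    unstable_fraction: float = 0.1
    im_fraction: float = 0.2
    im_effect: float = 2.0
    n_informative_im: int = 20
    batch_shift_sd: float = 1.0

    def __post_init__(self):
        if len(self.subtype_names) < 2:
            raise ValidationError("need >=2 subtypes")
        if len(set(self.subtype_names)) != len(self.subtype_names):
            raise ValidationError("subtype names must be unique")
        for name in ("n_genes", "n_informative_per_subtype", "n_per_subtype"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("dual_fraction", "unstable_fraction", "im_fraction", "dual_mixing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.dual_fraction + self.unstable_fraction > 1.0:
            raise ValidationError("dual_fraction + unstable_fraction must be <= 1")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValidationError("noise/shift standard deviations must be >= 0")
        needed = len(self.subtype_names) * self.n_informative_per_subtype + self.n_informative_im
        if needed > self.n_genes:
            raise ValidationError(
                f"{needed} informative genes do not fit in {self.n_genes} genes"
            )

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_names)

    @property
    def n_samples(self) -> int:
        return self.n_per_subtype * self.n_subtypes

    def with_(self, **kwargs) -> "SyntheticCohortSpec":
        return replace(self, **kwargs)


@dataclass
class PlantingRecord:
    """Ground truth for a generated cohort.

    ``samples`` has one row per sample: kind (single/dual/unstable), subtype
    (primary planted subtype or empty), dual_partner, im (bool), batch.
    ``gene_roles`` maps each gene to the subtype whose informative block it
    belongs to, ``"IM"`` for the overlay block, or ``""`` for background.
    """

    samples: pd.DataFrame
    gene_roles: pd.Series = field(repr=False)

    def true_singles(self) -> pd.Series:
        """Planted subtype of every single-subtype sample."""
        mask = self.samples["kind"] == "single"
        return self.samples.loc[mask, "subtype"]


def _gene_ids(spec: SyntheticCohortSpec) -> list[str]:
    width = len(str(spec.n_genes))
    return [f"g{str(i).zfill(width)}" for i in range(1, spec.n_genes + 1)]


def _gene_roles(spec: SyntheticCohortSpec) -> pd.Series:
    roles = pd.Series("", index=pd.Index(_gene_ids(spec), name="gene"), dtype=object)
    pos = 0
    for name in spec.subtype_names:
        roles.iloc[pos : pos + spec.n_informative_per_subtype] = name
        pos += spec.n_informative_per_subtype
    if spec.n_informative_im:
        roles.iloc[pos : pos + spec.n_informative_im] = "IM"
    return roles


def generate_centroids(spec: SyntheticCohortSpec) -> CentroidSet:
    """Centroid table on the centered log2 scale (the classifier's input contract).

    Each subtype is elevated on its own disjoint informative block and
    depressed on the other subtypes' blocks: +separation*(1 - 1/K) on its own
    block, -separation/K on the K-1 other blocks, 0 on background and IM
    genes — i.e. the per-gene centered image of disjoint +separation blocks
    in a balanced K-subtype cohort.  A zero-noise sample therefore reproduces
    its centroid exactly (rho = 1) after the log2 + centering pipeline.  The
    IM centroid is +im_effect on the IM block.  Deterministic (the layout
    involves no randomness).
    """
    if spec.separation == 0:
        log.warning("separation is 0: all centroids are identical (degenerate cohort)")
    roles = _gene_roles(spec)
    k = spec.n_subtypes
    data = pd.DataFrame(0.0, index=roles.index, columns=list(spec.subtype_names))
    informative = roles.isin(spec.subtype_names)
    for name in spec.subtype_names:
        data.loc[informative, name] = -spec.separation / k
        data.loc[roles == name, name] = spec.separation * (1.0 - 1.0 / k)
    im = None
    if spec.n_informative_im:
        im = pd.Series(0.0, index=roles.index)
        im[roles == "IM"] = spec.im_effect
    return CentroidSet(data, im_centroid=im, algorithm_label=f"synthetic-{spec.n_genes}-gene")


def _plan_samples(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    n_dual = round(spec.dual_fraction * n)
    n_uns = round(spec.unstable_fraction * n)
    n_single = n - n_dual - n_uns
    kinds = ["single"] * n_single + ["dual"] * n_dual + ["unstable"] * n_uns
    subtypes, partners = [], []
    for i, kind in enumerate(kinds):
        if kind == "single":
            subtypes.append(spec.subtype_names[i % spec.n_subtypes])
            partners.append("")
        elif kind == "dual":
            a, b = rng.choice(spec.n_subtypes, size=2, replace=False)
            subtypes.append(spec.subtype_names[a])
            partners.append(spec.subtype_names[b])
        else:
            subtypes.append("")
            partners.append("")
    im = rng.random(n) < spec.im_fraction
    width = len(str(n))
    ids = [f"s{str(i).zfill(width)}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "kind": kinds,
            "subtype": subtypes,
            "dual_partner": partners,
            "im": im,
            "batch": "invitro",
        },
        index=pd.Index(ids, name="sample"),
    )


def generate_cohort(
    spec: SyntheticCohortSpec, centroids: CentroidSet | None = None
) -> tuple[ExpressionMatrix, PlantingRecord]:
    """Draw a cohort around the centroids; returns a linear-scale matrix.

    log2 profile of a single sample = its centroid + N(0, noise_sd) per gene;
    a dual sample mixes two centroids with weight ``dual_mixing``; an unstable
    sample is pure noise.  IM-positive samples additionally get +im_effect on
    the IM gene block.  Values are emitted as 2**x (FPKM-like, strictly
    positive).  Bit-deterministic in the seed.
    """
    if centroids is None:
        centroids = generate_centroids(spec)
    roles = _gene_roles(spec)
    if list(centroids.gene_ids) != list(roles.index):
        raise ValidationError("centroids do not match the spec's gene layout")
    root = np.random.SeedSequence(spec.seed)
    plan_ss, sample_ss = root.spawn(2)
    plan = _plan_samples(spec, np.random.default_rng(plan_ss))
    im_block = (roles == "IM").to_numpy()

    streams = sample_ss.spawn(len(plan))
    profiles = np.empty((spec.n_genes, len(plan)))
    for j, (sample, row) in enumerate(plan.iterrows()):
        rng = np.random.default_rng(streams[j])
        if row["kind"] == "single":
            base = centroids.data[row["subtype"]].to_numpy(dtype=float)
        elif row["kind"] == "dual":
            base = spec.dual_mixing * centroids.data[row["subtype"]].to_numpy(dtype=float) + (
                1.0 - spec.dual_mixing
            ) * centroids.data[row["dual_partner"]].to_numpy(dtype=float)
        else:
            base = np.zeros(spec.n_genes)
        profile = base + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
        if row["im"]:
            profile = profile + spec.im_effect * im_block
        profiles[:, j] = profile

    data = pd.DataFrame(
        np.exp2(profiles), index=roles.index.copy(), columns=plan.index.copy()
    )
    matrix = ExpressionMatrix(
        data, scale=Scale.LINEAR, batch=pd.Series("invitro", index=plan.index)
    )
    return matrix, PlantingRecord(samples=plan, gene_roles=roles)


def apply_condition_shift(
    matrix: ExpressionMatrix,
    spec: SyntheticCohortSpec,
    condition: str = "xenograft",
) -> ExpressionMatrix:
    """Additive per-gene log2 shift shared by all samples of a condition.

    Emulates a platform/microenvironment offset between conditions: the same
    N(0, batch_shift_sd) draw is added to every sample's log2 value of a gene
    (i.e. the linear values are scaled by 2**shift).  Per-gene centering
    within the shifted batch removes the shift exactly.  Deterministic in the
    spec's seed (a dedicated stream, independent of the cohort draws).
    """
    if matrix.scale is not Scale.LINEAR:
        raise ValidationError("condition shift expects the linear-scale cohort matrix")
    shift_ss = np.random.SeedSequence(spec.seed).spawn(3)[2]
    rng = np.random.default_rng(shift_ss)
    shift = rng.normal(0.0, spec.batch_shift_sd, size=matrix.n_genes)
    shifted = matrix.data.mul(np.exp2(shift), axis=0)
    return ExpressionMatrix(
        shifted,
        scale=Scale.LINEAR,
        batch=pd.Series(condition, index=matrix.data.columns),
    )
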