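# Methods

## Classification model

Each sample is represented by a per-gene expression profile on the
log2-transformed, per-gene batch-centered scale; each subtype by a centroid
profile over the same genes, assumed to be on that same centered scale (the
centroid table is an input contract — this package does not re-center
centroids against the cohort).  Spearman's rank correlation is used because
expression relationships between platforms and conditions are expected to be
monotone but not linear; it also makes calls invariant to any strictly
increasing transform of a sample's processed profile.

The decision procedure is a strict-threshold candidate rule followed by a
pairwise significance test:

1. candidates: subtypes with ρ **strictly greater** than the cutoff
   (default 0.1; a correlation exactly at the cutoff is not a candidate);
2. zero candidates → UNS; one → single subtype;
3. two or more → the top candidate is tested against each other candidate
   with z = (atanh ρ_a − atanh ρ_b)/√(2·1.06/(n−3)), where n is the number of
   genes actually used in the correlations and 1.06/(n−3) is the
   Fieller-adjusted variance of a Fisher-transformed Spearman correlation.
   Candidates not significantly below the top (two-sided, α = 0.05) join a
   dual-subtype list ranked by correlation; if all are significantly lower
   the predominant subtype is assigned alone.

The two correlations being compared share the sample profile, so they are not
independent; a Steiger-style dependent-correlation variant is available via
`ClassifierConfig(tie_test="steiger")`, which accepts the correlation between
the two centroid profiles (0 when unknown).  The independent-sample Fisher
form is the default because it needs no extra input and is conservative in
the relevant direction (it under-rejects, so borderline pairs are reported as
dual rather than silently collapsed to one subtype).

IM (immunomodulatory) status is an overlay, not a subtype: when the centroid
table carries an IM column the sample is IM-positive iff its Spearman
correlation with that profile exceeds the IM cutoff (default 0.1, matching
the subtype cutoff); without an IM column the status is *undetermined*.

### Numerical choices and degenerate inputs

* |ρ| = 1 is clipped to 1 − 1e-7 before atanh (logged at debug level); the z
  statistic stays finite and such a pair is always significant.
* Exact ρ ties at the top are ordered alphabetically for determinism; a zero
  difference is never significant, so tied tops always produce a dual call.
* A zero-variance profile (e.g. a single-sample batch after centering) has no
  defined rank correlation: all ρ are NaN, treated as below any cutoff, and
  the sample is called UNS with a warning.
* Signature genes absent from the matrix are dropped from the correlation
  (never imputed) and `n_genes_used` records the reduction; classification is
  refused outright when the missing fraction strictly exceeds 10% (a matrix
  missing exactly 10% still passes).
* At least 3 shared genes are required for a correlation and at least 4 for
  the z test (its variance uses n − 3).

## Preprocessing

`log2(x + pseudocount)` with pseudocount 1.0 by default, because FPKM
matrices contain zeros.  When a matrix is known to be strictly positive
(e.g. the synthetic cohorts below, which are exponentials of Gaussians) a
pseudocount of 0 makes the transform the exact inverse of the generator; the
shift-neutralization tests use that setting, since the pseudocount's
nonlinearity otherwise perturbs the cancellation at the 1e-2 level without
changing calls.

"Centering" is mean-centering by default (the usual convention for centroid
classifiers), median by configuration.  Centering is per gene within each
batch; with no batch labels the whole matrix is one batch.  The centering
statistic is computed on the per-gene sorted values so that it is
bit-identical under any permutation of samples — equal expression values
remain exactly tied after centering, which matters because the downstream
statistic is rank-based.  Single-sample batches are permitted with a warning:
their profiles center to zero and classify as UNS, which is the honest
outcome for a sample that cannot be normalized against peers.

## Signature reduction (nearest shrunken centroids)

Standard formulation: per gene i and class k, the standardized deviation
d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)) with m_k = √(1/n_k − 1/n), s_i the
pooled within-class standard deviation and s0 the median of the s_i, is
soft-thresholded by Δ; genes with any surviving deviation form the signature,
and shrunken centroids are reconstructed as x̄_i + m_k (s_i + s0) d′_ik.  At
Δ = 0 the shrunken centroids equal the raw class means exactly, and the
signature size is non-increasing in Δ.  Δ is chosen by stratified k-fold
cross-validation (scikit-learn folds, explicit seed) minimizing
misclassification of the shrunken-centroid discriminant with equal class
priors; ties break toward the larger Δ, i.e. the smaller signature.

Deliberate hybrid: the *trainer* classifies by the Gaussian discriminant
during cross-validation, but the exported reduced centroid table is consumed
by the Spearman correlation classifier.  This mirrors how reduced clinical
signatures are derived from large discovery gene sets by shrinkage and then
deployed through a simpler correlation rule.

## Concordance and stability

Two calls match when both carry the same non-UNS primary subtype; matching is
on the primary (highest-correlation) subtype only, with an optional lenient
rule that also accepts a dual-list partner.  UNS never matches anything —
including another UNS call, since two failures to classify are not evidence
of the same biology.  The sample set partitions exactly into matched,
mismatched (both non-UNS, different subtype) and UNS-involving pairs.
Per-subtype agreement is grouped by the reference (first) call set's subtype
and is therefore direction-dependent; the overall match count is symmetric.
A sample is stable across conditions when every condition in which it appears
(conditions missing the sample are skipped, not penalized) assigns the same
non-UNS primary subtype.

The packaged call tables (`tnbcsubtype/data/`) transcribe the published
subtype calls of a 17-line TNBC panel under the 2188-gene and 101-gene
classifiers, in vitro and as xenografts, and of the six stable lines across
five expression sources.  They carry only the reported primary/dual
correlations, so loaded calls have no full correlation vector.

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes, not
real RNA-seq: K = 5 subtypes with disjoint 20-gene informative blocks in a
500-gene background; Gaussian log2-scale noise (sd 1.0); samples drawn as
single (centroid + noise), dual (50:50 centroid mixture + noise, 10% of the
cohort), or unstable (pure noise, 10%); a 20-gene IM overlay block added to a
random 20% of samples (+2 log2 units); and an additive per-gene condition
shift (sd 1.0) shared by all samples of a condition, emulating the
platform/microenvironment offset between culture and xenograft.  Values are
exponentiated to an FPKM-like linear scale so the whole pipeline, including
the log2 transform, is exercised.  Defaults (100 samples, separation 2.0
log2 units, noise sd 1.0) were chosen once as a desk-scale cohort with
realistic signal-to-noise for a bulk expression signature: per-subtype
Spearman correlations of true singles land around 0.3–0.4, comfortably above
the 0.1 cutoff but far from 1, which is the regime the published correlation
values occupy.

Centroids are emitted on the **centered** scale: +sep·(1 − 1/K) on the own
block and −sep/K on the other blocks — the per-gene centered image of
disjoint +sep blocks in a balanced cohort.  This keeps the generator
consistent with the classifier's input contract and makes the zero-noise
cohort an exact fixed point: every sample's processed profile is a strictly
monotone map of its centroid and correlates at exactly 1.0.

Randomness is hierarchical (`numpy` SeedSequence): the root seed spawns one
stream for the cohort plan, one per sample, and one for the condition shift,
so enlarging a cohort does not reshuffle earlier samples' draws.  A seed is
mandatory everywhere; there is no silent entropy.

### What passing on synthetic data does and does not show

The generator has independent Gaussian noise, disjoint informative blocks and
no correlation structure between genes, no library-size or GC effects, no
count-level sampling noise, no tumor purity or mouse-read contamination in
the "xenograft" condition.  Recovery and neutralization results on it
validate the *procedure* (decision logic, rank statistics, centering algebra,
shrinkage arithmetic) — they are not evidence about classification accuracy
on real tumors, where signatures overlap and batch effects are not purely
additive.

## Problem sizes

The default test and acceptance workloads are desk-scale by design: the
17-line published panel, 100-sample × 500-gene synthetic cohorts, shrinkage
training on the 80 single-subtype samples, and 200 random small profiles for
the rank-oracle comparison.  The full test suite runs in well under a minute
on one CPU.

## Known limitations

* Gene identifiers are matched as exact case-sensitive strings; no
  symbol/alias mapping.
* The IM scorer is a plain overlay-centroid correlation with its own cutoff;
  published IM callers use a separately trained model whose parameters are
  not public, so IM mechanics here are a documented stand-in.
* The published correlation values for the cell-line panel are inputs
  (transcribed calls), not recomputed — doing so would require the original
  expression cohorts and proprietary centroid tables.
* Cross-platform normalization beyond per-batch gene centering (quantile
  normalization, empirical-Bayes batch correction) is out of scope.
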