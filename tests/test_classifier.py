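import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbcsubtype import (
    CallStatus,
    CentroidSet,
    ClassifierConfig,
    CorrelationVector,
    CoverageError,
    ExpressionMatrix,
    IMStatus,
    Scale,
    ValidationError,
    assess_im_status,
    call_subtype,
    classify_cohort,
    correlate_to_centroids,
    compare_correlations,
)
from conftest import spearman_bruteforce

SUBTYPES = ["BL1", "BL2", "M", "LAR", "MSL"]


def _centroids_from(columns: dict) -> CentroidSet:
    return CentroidSet(pd.DataFrame(columns, index=[f"g{i}" for i in range(
        len(next(iter(columns.values()))))]))


def _vector(rhos: dict, n=101) -> CorrelationVector:
    return CorrelationVector(rhos, n)


class TestSpearmanCorrelation:
    def test_self_correlation_is_one(self):
        vals = [0.3, -1.2, 0.8, 2.0, -0.5]
        cen = _centroids_from({"BL1": vals, "BL2": [0, 1, 2, 3, 4]})
        profile = pd.Series(vals, index=cen.data.index)
        cv = correlate_to_centroids(profile, cen)
        assert cv.rho["BL1"] == pytest.approx(1.0)
        assert cv.n_genes_used == 5

    def test_monotone_transform_of_centroid_still_one(self):
        vals = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
        cen = _centroids_from({"M": vals.tolist(), "BL1": [4, 3, 2, 1, 0]})
        profile = pd.Series(vals**3, index=cen.data.index)  # strictly increasing map
        assert correlate_to_centroids(profile, cen).rho["M"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        cen = _centroids_from({"A": [5, 4, 3, 2, 1], "B": [1, 2, 3, 4, 5]})
        profile = pd.Series([1, 2, 3, 4, 5], index=cen.data.index, dtype=float)
        assert correlate_to_centroids(profile, cen).rho["A"] == pytest.approx(-1.0)

    def test_six_gene_tie_case_matches_rank_oracle(self):
        # one tied pair in the sample; expected value frozen from explicit
        # average-rank arithmetic
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        cen = _centroids_from({"A": y, "B": y[::-1]})
        profile = pd.Series(x, index=cen.data.index)
        rho = correlate_to_centroids(profile, cen).rho["A"]
        assert rho == pytest.approx(0.753702346348183, abs=1e-12)

    def test_intersection_only_and_n_recorded(self):
        cen = _centroids_from({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        profile = pd.Series([10.0, 20.0, 30.0, 5.0],
                            index=["g0", "g1", "g2", "not_in_centroids"])
        cv = correlate_to_centroids(profile, cen)
        assert cv.n_genes_used == 3
        assert cv.rho["A"] == pytest.approx(1.0)

    def test_fewer_than_three_shared_genes_rejected(self):
        cen = _centroids_from({"A": [1, 2, 3], "B": [3, 2, 1]})
        profile = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(ValidationError):
            correlate_to_centroids(profile, cen)

    def test_zero_variance_profile_flagged_nan(self):
        cen = _centroids_from({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        profile = pd.Series([2.0] * 4, index=cen.data.index)
        cv = correlate_to_centroids(profile, cen)
        assert all(math.isnan(r) for r in cv.rho.values())
        call = call_subtype(cv)
        assert call.status is CallStatus.UNSTABLE

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(4, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(-5, 5), min_size=n, max_size=n),
                st.lists(st.integers(-5, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_bruteforce_oracle_on_small_inputs(self, xy):
        x, y = xy
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        cen = _centroids_from({"A": [float(v) for v in y],
                               "B": [float(v) for v in y[::-1]]})
        profile = pd.Series([float(v) for v in x], index=cen.data.index)
        rho = correlate_to_centroids(profile, cen).rho["A"]
        expected = spearman_bruteforce(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)


class TestCorrelationDifference:
    def test_equal_rhos_z_zero_not_significant(self):
        z, sig = compare_correlations(0.4, 0.4, 50)
        assert z == 0.0 and not sig

    def test_close_pair_at_n101_not_significant(self):
        z, sig = compare_correlations(0.27, 0.17, 101)
        assert z == pytest.approx(0.715235594128533, abs=1e-12)
        assert not sig

    def test_distant_pair_at_n101_significant(self):
        z, sig = compare_correlations(0.9, 0.0, 101)
        assert z == pytest.approx(10.009621835633066, abs=1e-9)
        assert sig

    def test_antisymmetric(self):
        z_ab, _ = compare_correlations(0.5, 0.2, 40)
        z_ba, _ = compare_correlations(0.2, 0.5, 40)
        assert z_ab == pytest.approx(-z_ba)

    def test_rho_one_clipped_finite(self):
        z, sig = compare_correlations(1.0, 0.0, 101)
        assert math.isfinite(z) and sig

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_correlations(0.5, 0.1, 3)

    def test_steiger_variant_runs_and_agrees_in_sign(self):
        cfg = ClassifierConfig(tie_test="steiger")
        z, _ = compare_correlations(0.5, 0.2, 101, cfg, rho_centroids=0.3)
        assert z > 0


class TestCallSubtype:
    def test_no_candidate_is_unstable(self):
        cv = _vector({"BL1": 0.05, "BL2": 0.02, "M": -0.10, "LAR": 0.0, "MSL": 0.04})
        call = call_subtype(cv)
        assert call.status is CallStatus.UNSTABLE
        assert call.primary_subtype is None
        assert call.candidates_above_cutoff == []

    def test_single_candidate_assigned(self):
        cv = _vector({"BL1": 0.05, "BL2": 0.02, "M": -0.1, "LAR": 0.53, "MSL": 0.04})
        call = call_subtype(cv)
        assert call.status is CallStatus.SINGLE
        assert call.primary_subtype == "LAR"
        assert call.primary_rho == pytest.approx(0.53)
        assert call.dual_subtypes == []

    def test_two_close_candidates_dual_ranked(self):
        cv = _vector({"BL1": 0.0, "BL2": 0.27, "M": 0.17, "LAR": 0.05, "MSL": -0.2})
        call = call_subtype(cv)
        assert call.status is CallStatus.DUAL
        assert call.primary_subtype == "BL2"
        assert call.dual_subtypes == [("BL2", 0.27), ("M", 0.17)]

    def test_dominant_candidate_over_weak_one_is_single(self):
        cv = _vector({"BL1": 0.9, "BL2": 0.12, "M": 0.0, "LAR": 0.0, "MSL": 0.0})
        call = call_subtype(cv)
        assert call.status is CallStatus.SINGLE
        assert call.primary_subtype == "BL1"
        assert call.candidates_above_cutoff == ["BL1", "BL2"]

    def test_rho_exactly_at_cutoff_is_not_a_candidate(self):
        cv = _vector({"BL1": 0.1, "BL2": 0.1, "M": 0.1, "LAR": 0.1, "MSL": 0.1})
        assert call_subtype(cv).status is CallStatus.UNSTABLE

    def test_exact_tie_at_top_is_dual_alphabetical(self):
        cv = _vector({"M": 0.3, "BL2": 0.3, "BL1": 0.0, "LAR": 0.0, "MSL": 0.0})
        call = call_subtype(cv)
        assert call.status is CallStatus.DUAL
        assert call.primary_subtype == "BL2"  # alphabetical among exact ties
        assert call.dual_subtypes == [("BL2", 0.3), ("M", 0.3)]

    def test_three_way_dual_keeps_all_nonsignificant(self):
        cv = _vector({"BL1": 0.25, "BL2": 0.24, "M": 0.22, "LAR": 0.0, "MSL": 0.0})
        call = call_subtype(cv)
        assert call.status is CallStatus.DUAL
        assert [n for n, _ in call.dual_subtypes] == ["BL1", "BL2", "M"]

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(
            st.floats(min_value=-0.999, max_value=0.999, allow_nan=False),
            min_size=5, max_size=5,
        )
    )
    def test_decision_tree_exhaustive_and_consistent(self, rhos):
        """Every correlation vector yields exactly one of single/dual/unstable,
        with the strict-cutoff and ranking rules respected."""
        cfg = ClassifierConfig()
        cv = _vector(dict(zip(SUBTYPES, rhos)))
        call = call_subtype(cv, cfg)
        candidates = [s for s, r in cv.rho.items() if r > cfg.cutoff]
        assert call.status in (CallStatus.SINGLE, CallStatus.DUAL, CallStatus.UNSTABLE)
        if not candidates:
            assert call.status is CallStatus.UNSTABLE
            assert call.primary_subtype is None
        else:
            assert call.status is not CallStatus.UNSTABLE
            assert set(call.candidates_above_cutoff) == set(candidates)
            assert call.primary_rho == max(cv.rho[s] for s in candidates)
            assert call.primary_rho > cfg.cutoff
            if call.status is CallStatus.DUAL:
                rho_list = [r for _, r in call.dual_subtypes]
                assert rho_list == sorted(rho_list, reverse=True)
                assert call.dual_subtypes[0][0] == call.primary_subtype

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-0.99, 0.99, allow_nan=False), min_size=5, max_size=5),
        st.floats(0.0, 0.5),
    )
    def test_raising_cutoff_never_rescues_uns(self, rhos, delta_cutoff):
        cv = _vector(dict(zip(SUBTYPES, rhos)))
        low = call_subtype(cv, ClassifierConfig(cutoff=0.1))
        high = call_subtype(cv, ClassifierConfig(cutoff=0.1 + delta_cutoff))
        if low.status is CallStatus.UNSTABLE:
            assert high.status is CallStatus.UNSTABLE


class TestIMStatus:
    def test_profile_equal_to_im_centroid_positive(self, small_centroids):
        profile = small_centroids.im_centroid.copy()
        assert assess_im_status(profile, small_centroids) is IMStatus.POSITIVE

    def test_anticorrelated_profile_negative(self, small_centroids):
        profile = -small_centroids.im_centroid
        assert assess_im_status(profile, small_centroids) is IMStatus.NEGATIVE

    def test_no_im_centroid_undetermined(self, small_centroids):
        cen = CentroidSet(small_centroids.data.copy())
        profile = small_centroids.data["BL1"]
        assert assess_im_status(profile, cen) is IMStatus.UNDETERMINED


class TestClassifyCohort:
    def _cohort(self, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        cen = CentroidSet(
            pd.DataFrame(rng.normal(size=(n_genes, 3)), index=genes,
                         columns=["BL1", "BL2", "M"])
        )
        profiles = pd.DataFrame(
            {f"s_{c}": np.exp2(cen.data[c]) for c in cen.subtype_names},
            index=genes,
        )
        return cen, ExpressionMatrix(profiles, scale=Scale.LINEAR)

    def test_sample_order_permutation_permutes_calls(self, default_cohort, default_calls):
        _, centroids, matrix, _ = default_cohort
        perm = matrix.sample_ids[::-1]
        permuted = ExpressionMatrix(matrix.data[perm], scale=matrix.scale)
        calls_perm = classify_cohort(permuted, centroids)
        by_id = {c.sample_id: c for c in default_calls}
        assert [c.sample_id for c in calls_perm] == perm
        for c in calls_perm:
            assert c.label == by_id[c.sample_id].label
            assert c.status == by_id[c.sample_id].status

    def test_gene_order_permutation_leaves_calls_unchanged(self):
        cen, matrix = self._cohort()
        calls = classify_cohort(matrix, cen)
        order = matrix.gene_ids[::-1]
        cen_p = CentroidSet(cen.data.loc[order])
        mat_p = ExpressionMatrix(matrix.data.loc[order], scale=matrix.scale)
        calls_p = classify_cohort(mat_p, cen_p)
        for a, b in zip(calls, calls_p):
            assert (a.sample_id, a.label, a.status) == (b.sample_id, b.label, b.status)
            assert a.correlations.rho == pytest.approx(b.correlations.rho)

    def test_rank_invariance_to_monotone_map_of_processed_profile(self):
        # any strictly increasing function of a sample's centered profile
        # preserves ranks, hence its correlation vector and call
        from tnbcsubtype import preprocess

        cen, matrix = self._cohort()
        proc = preprocess(matrix)
        for sample in proc.sample_ids:
            profile = proc.data[sample]
            warped = profile**3  # odd power: strictly increasing on the reals
            cv = correlate_to_centroids(profile, cen)
            cv_w = correlate_to_centroids(warped, cen)
            assert cv_w.rho == pytest.approx(cv.rho, abs=1e-12)
            a, b = call_subtype(cv), call_subtype(cv_w)
            assert (a.label, a.status, a.dual_subtypes) == (b.label, b.status, b.dual_subtypes)

    def test_coverage_gate_refusal_carries_report(self):
        cen, matrix = self._cohort()
        truncated = ExpressionMatrix(matrix.data.iloc[10:], scale=matrix.scale)
        with pytest.raises(CoverageError) as exc:
            classify_cohort(truncated, cen)
        assert exc.value.report.missing_fraction == pytest.approx(0.25)

    def test_pure_noise_cohort_mostly_uns(self):
        rng = np.random.default_rng(123)
        n_genes = 400
        genes = [f"g{i}" for i in range(n_genes)]
        cen = CentroidSet(
            pd.DataFrame(rng.normal(size=(n_genes, 5)), index=genes, columns=SUBTYPES)
        )
        noise = pd.DataFrame(
            np.exp2(rng.normal(size=(n_genes, 60))), index=genes,
            columns=[f"s{i}" for i in range(60)],
        )
        calls = classify_cohort(ExpressionMatrix(noise, scale=Scale.LINEAR), cen)
        uns_fraction = sum(c.status is CallStatus.UNSTABLE for c in calls) / len(calls)
        # rho sd ~ 1/sqrt(399) ~ 0.05, so 0.1 is a two-sigma cutoff per subtype;
        # most uncorrelated samples must fail all five
        assert uns_fraction > 0.7
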