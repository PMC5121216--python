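import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atomicregulons.calling import OFF, ON, UNKNOWN, CallMatrix
from atomicregulons.genome import GeneCluster
from atomicregulons.inference import (
    CorrelationMatrix,
    accretion_split,
    ar_profile,
    infer_atomic_regulons,
    merge_by_profile,
    pcc_to_distance,
    pearson_matrix,
    split_by_pcc,
    transitive_merge,
)
from atomicregulons.io import ExpressionMatrix


def _corr(genes, entries):
    """Build a CorrelationMatrix from {(a, b): r} pairs (symmetric, diag 1)."""
    genes = list(genes)
    df = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    for (a, b), r in entries.items():
        df.at[a, b] = df.at[b, a] = r
    return CorrelationMatrix(df)


def _cluster(members, cid="c1"):
    return GeneCluster(cid, frozenset(members), "operon")


class TestPearson:
    def test_duplicate_row_and_negation(self, small_expr):
        corr = pearson_matrix(small_expr)
        # gB is monotone with gA but not identical; gC = 5 - gA exactly
        assert corr.pcc("gA", "gC") == pytest.approx(-1.0)
        assert corr.pcc("gA", "gA") == 1.0

    def test_hand_computed_coefficient(self):
        # x=(1,2,3,4), y=(1,2,3,5): cov*n = 6.5, ssx = 5, ssy = 8.75
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 5]], index=["x", "y"],
            columns=["e1", "e2", "e3", "e4"],
        ))
        expected = 6.5 / np.sqrt(5 * 8.75)
        assert pearson_matrix(expr).pcc("x", "y") == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_flagged_undefined(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "x"],
            columns=list("abcd"),
        ))
        with pytest.warns(UserWarning, match="undefined"):
            corr = pearson_matrix(expr)
        assert not corr.is_defined("flat", "x")
        assert corr.pcc("flat", "flat") == 1.0  # diagonal pinned

    def test_pairwise_complete_uses_shared_experiments(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2, 3, 4, np.nan], [2.0, 4, 6, 8, 100.0]], index=["x", "y"],
            columns=list("abcde"),
        ))
        assert pearson_matrix(expr).pcc("x", "y") == pytest.approx(1.0)


class TestDistance:
    @pytest.mark.parametrize("form", ["linear", "squared"])
    @pytest.mark.parametrize("pcc, expected", [(1.0, 0.0), (0.5, 0.25)])
    def test_known_points_both_forms(self, form, pcc, expected):
        assert pcc_to_distance(pcc, form) == expected

    def test_extremes_linear(self):
        assert pcc_to_distance(-1.0) == 1.0
        assert pcc_to_distance(1.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pcc_to_distance(1.5)

    @given(st.floats(min_value=-1.0, max_value=1.0), st.floats(min_value=-1.0, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_form_is_strictly_monotone_bijection(self, a, b):
        da, db = pcc_to_distance(a), pcc_to_distance(b)
        assert 0.0 <= da <= 1.0
        if a < b:
            assert da >= db
            if b - a > 1e-9:  # strictly decreasing at resolvable spacing
                assert da > db
        elif a == b:
            assert da == db


class TestSplitByPcc:
    def test_compliant_cluster_unchanged(self):
        corr = _corr("ABC", {("A", "B"): 0.9, ("A", "C"): 0.9, ("B", "C"): 0.9})
        out = split_by_pcc(_cluster("ABC"), corr)
        assert [sorted(c.members) for c in out] == [["A", "B", "C"]]

    def test_weakly_linked_gene_split_off(self):
        corr = _corr("ABC", {("A", "B"): 0.9, ("A", "C"): 0.2, ("B", "C"): 0.2})
        out = split_by_pcc(_cluster("ABC"), corr)
        assert sorted(sorted(c.members) for c in out) == [["A", "B"], ["C"]]

    def test_all_subthreshold_gives_singletons(self):
        corr = _corr("ABC", {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5})
        out = split_by_pcc(_cluster("ABC"), corr)
        assert sorted(sorted(c.members) for c in out) == [["A"], ["B"], ["C"]]

    def test_exhaustive_partition_criterion_on_random_triples(self):
        # every multi-gene output must be a clique above threshold, and the
        # outputs must partition the input (oracle: direct checks over all
        # random instances)
        rng = np.random.default_rng(11)
        for _ in range(200):
            entries = {
                ("A", "B"): rng.uniform(-1, 1),
                ("A", "C"): rng.uniform(-1, 1),
                ("B", "C"): rng.uniform(-1, 1),
            }
            corr = _corr("ABC", entries)
            out = split_by_pcc(_cluster("ABC"), corr, threshold=0.7)
            members = sorted(g for c in out for g in c.members)
            assert members == ["A", "B", "C"]
            for c in out:
                for a, b in itertools.combinations(sorted(c.members), 2):
                    assert corr.pcc(a, b) > 0.7


class TestTransitiveMerge:
    def test_shared_gene_merges(self):
        out = transitive_merge([_cluster("AB", "c1"), _cluster("BC", "c2")])
        assert [sorted(c.members) for c in out] == [["A", "B", "C"]]

    def test_disjoint_clusters_unchanged(self):
        out = transitive_merge([_cluster("AB", "c1"), _cluster("CD", "c2")])
        assert sorted(sorted(c.members) for c in out) == [["A", "B"], ["C", "D"]]


class TestAccretionSplit:
    def test_tight_cluster_not_split(self):
        corr = _corr("ABC", {("A", "B"): 0.8, ("A", "C"): 0.8, ("B", "C"): 0.8})
        out = accretion_split(_cluster("ABC"), corr)
        assert [sorted(c.members) for c in out] == [["A", "B", "C"]]

    def test_two_tight_blocks_split_apart(self):
        # d(A,B)=d(C,D)=0.05 -> pcc 0.9; cross distance 0.9 -> pcc -0.8
        corr = _corr(
            "ABCD",
            {("A", "B"): 0.9, ("C", "D"): 0.9,
             ("A", "C"): -0.8, ("A", "D"): -0.8, ("B", "C"): -0.8, ("B", "D"): -0.8},
        )
        out = accretion_split(_cluster("ABCD"), corr)
        assert sorted(sorted(c.members) for c in out) == [["A", "B"], ["C", "D"]]

    def test_pair_at_exact_cutoff_joined(self):
        # pcc 0.5 -> distance exactly 0.25, inclusive threshold
        corr = _corr("AB", {("A", "B"): 0.5})
        out = accretion_split(_cluster("AB"), corr)
        assert [sorted(c.members) for c in out] == [["A", "B"]]

    def test_pair_beyond_cutoff_split(self):
        corr = _corr("AB", {("A", "B"): 0.4})  # distance 0.3 > 0.25
        out = accretion_split(_cluster("AB"), corr)
        assert sorted(sorted(c.members) for c in out) == [["A"], ["B"]]


class TestProfiles:
    calls = CallMatrix(pd.DataFrame(
        [[ON, ON], [ON, OFF], [OFF, OFF]], index=["a", "b", "c"],
        columns=["e1", "e2"], dtype=np.int8,
    ))

    @pytest.mark.parametrize(
        "members, expected",
        [({"a"}, (ON, ON)), ({"a", "b"}, (ON, UNKNOWN)), ({"a", "b", "c"}, (ON, OFF))],
    )
    def test_plurality_profiles(self, members, expected):
        assert ar_profile(members, self.calls) == expected

    def test_identical_profiles_merge_into_always_on(self):
        calls = CallMatrix(pd.DataFrame(
            [[ON, ON], [ON, ON], [ON, ON], [OFF, ON]],
            index=list("abcd"), columns=["e1", "e2"], dtype=np.int8,
        ))
        ars = merge_by_profile([_cluster("ab", "c1"), _cluster("c", "c2"), _cluster("d", "c3")], calls)
        by_members = {frozenset(a.members): a for a in ars}
        merged = by_members[frozenset("abc")]
        assert merged.is_always_on and not merged.is_always_off
        assert by_members[frozenset("d")].profile == (OFF, ON)

    def test_merge_is_order_independent(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(9)]
        calls = CallMatrix(pd.DataFrame(
            rng.choice([ON, OFF, UNKNOWN], size=(9, 3)), index=genes,
            columns=["e1", "e2", "e3"], dtype=np.int8,
        ))
        clusters = [_cluster(genes[i : i + 3], f"c{i}") for i in range(0, 9, 3)]
        base = merge_by_profile(clusters, calls)
        for perm in itertools.permutations(clusters):
            out = merge_by_profile(list(perm), calls)
            assert [(a.ar_id, a.members) for a in out] == [(a.ar_id, a.members) for a in base]


class TestFullPipeline:
    def test_planted_blocks_recovered(self, default_dataset, default_result):
        from atomicregulons import planted_block_ari

        _, _, _, truth = default_dataset
        assert planted_block_ari(default_result, truth) >= 0.9

    def test_ars_are_pairwise_disjoint_and_conserve_genes(self, default_dataset, default_result):
        expr = default_dataset[0]
        seen = [g for a in default_result.ars for g in a.members]
        assert len(seen) == len(set(seen))
        assert sorted(seen) == sorted(expr.gene_ids)

    def test_summary_metrics_recomputable_from_ar_list(self, default_result):
        multi = [a for a in default_result.ars if len(a) >= 2]
        assert default_result.n_multigene_ars == len(multi)
        assert default_result.genes_in_multigene_ars == sum(len(a) for a in multi)

    def test_single_experiment_degenerates_to_profile_ars(self, default_dataset):
        expr, features, roles, truth = default_dataset
        one = ExpressionMatrix(expr.data.iloc[:, :1].copy())
        with pytest.warns(UserWarning):
            result = infer_atomic_regulons(one, features, roles, truth.always_on)
        # no PCC is defined, so multi-gene ARs can only come from profile merges
        assert all(len(a.profile) == 1 for a in result.ars)
        seen = [g for a in result.ars for g in a.members]
        assert sorted(seen) == sorted(expr.gene_ids)

    def test_rerun_is_deterministic(self, default_dataset, default_result):
        expr, features, roles, truth = default_dataset
        again = infer_atomic_regulons(expr, features, roles, truth.always_on)
        assert [(a.ar_id, a.members, a.profile) for a in again.ars] == [
            (a.ar_id, a.members, a.profile) for a in default_result.ars
        ]
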