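import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atomicregulons.evaluation import (
    CLRResult,
    best_jaccard_per_regulon,
    clr_cutoff,
    clr_scores,
    crossval_jaccard,
    jaccard,
    role_set_jaccard,
    subsample_sensitivity,
    support_fraction,
    support_report,
)
from atomicregulons.inference import infer_atomic_regulons
from atomicregulons.io import ExpressionMatrix, RegulonReference, RoleMap


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({"x"}, {"x"}, 1.0), ({"x"}, {"y"}, 0.0), ({"a", "b"}, {"b", "c"}, 1 / 3)],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @given(
        st.sets(st.integers(0, 12), max_size=8),
        st.sets(st.integers(0, 12), max_size=8),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_properties_against_set_oracle(self, a, b):
        if not a and not b:
            return
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)
        assert j == len(a & b) / len(a | b)

    def test_best_per_regulon_max_match(self):
        ref = RegulonReference({"R": {"a", "b", "c"}})
        best = best_jaccard_per_regulon(ref, [{"a", "b"}, {"c", "d"}])
        assert best["R"] == pytest.approx(2 / 3)

    def test_exact_cluster_match_scores_one(self):
        ref = RegulonReference({"R": {"a", "b"}})
        assert best_jaccard_per_regulon(ref, [{"a", "b"}, {"c"}])["R"] == 1.0

    def test_empty_cluster_list_gives_zeros_with_warning(self):
        ref = RegulonReference({"R": {"a"}})
        with pytest.warns(UserWarning):
            best = best_jaccard_per_regulon(ref, [])
        assert (best == 0.0).all()


@pytest.fixture(scope="module")
def independent_expr():
    rng = np.random.default_rng(42)
    genes = [f"g{i:02d}" for i in range(20)]
    return ExpressionMatrix(pd.DataFrame(
        rng.normal(size=(20, 200)), index=genes,
        columns=[f"e{j}" for j in range(200)],
    ))


class TestCLRScores:
    def test_scores_symmetric_nonnegative(self, independent_expr):
        scores = clr_scores(independent_expr).scores.to_numpy()
        assert np.allclose(scores, scores.T)
        assert (scores >= 0).all()

    def test_independent_profiles_rarely_supported(self, independent_expr):
        result = clr_cutoff(clr_scores(independent_expr), k_sd=4)
        assert result.cutoff > float(np.mean(result.pair_scores()))
        assert result.fraction_retained <= 0.05

    def test_identical_profiles_score_highest(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        rows = {"x": x, "y": x.copy()}
        for i in range(8):
            rows[f"n{i}"] = rng.normal(size=60)
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=[f"e{j}" for j in range(60)]
        ).T)
        result = clr_scores(expr)
        assert result.scores.at["x", "y"] == result.scores.to_numpy().max()

    def test_constant_gene_warns_and_scores_zero_mi(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0] * 10, list(range(10))], index=["flat", "x"],
            columns=[f"e{j}" for j in range(10)],
        ))
        with pytest.warns(UserWarning):
            clr_scores(expr)


class TestCLRCutoff:
    def _result_from_scores(self, n, entries):
        genes = [f"g{i:03d}" for i in range(n)]
        df = pd.DataFrame(0.0, index=genes, columns=genes)
        for (i, j), v in entries.items():
            df.iat[i, j] = df.iat[j, i] = v
        return CLRResult(df)

    def test_all_equal_scores_degenerate_to_all_supported(self):
        res = self._result_from_scores(4, {(i, j): 5.0 for i in range(4) for j in range(i + 1, 4)})
        with pytest.warns(UserWarning, match="zero SD"):
            out = clr_cutoff(res, k_sd=4)
        assert out.cutoff == 5.0
        assert len(out.supported_pairs) == math.comb(4, 2)

    def test_single_outlier_against_hand_mean_sd(self):
        # 142 genes -> 10011 pairs; one score of 100, rest 0.
        # mean = 100/10011; sd = sqrt(100^2/10011 - mean^2) ~ 0.99895
        # cutoff = mean + 4 sd ~ 4.006 -> only the outlier passes
        n_pairs = math.comb(142, 2)
        res = self._result_from_scores(142, {(0, 1): 100.0})
        out = clr_cutoff(res, k_sd=4)
        mean = 100.0 / n_pairs
        sd = math.sqrt(100.0**2 / n_pairs - mean**2)
        assert out.cutoff == pytest.approx(mean + 4 * sd)
        assert out.supported_pairs == {frozenset(("g000", "g001"))}

    def test_supported_set_antitone_in_k_sd(self):
        rng = np.random.default_rng(0)
        entries = {(i, j): rng.exponential() for i in range(12) for j in range(i + 1, 12)}
        res = self._result_from_scores(12, entries)
        supported = [clr_cutoff(res, k_sd=k).supported_pairs for k in (0, 1, 2, 4)]
        for bigger, smaller in zip(supported, supported[1:]):
            assert smaller <= bigger


class TestSupportFraction:
    def test_three_gene_worked_example(self):
        rep = support_fraction({"A", "B", "C"}, {frozenset("AB"), frozenset("AC")})
        assert rep.n_pairs == 3 and rep.n_supported == 2
        assert rep.fraction == pytest.approx(2 / 3)
        assert rep.bin == "60-80%"

    @pytest.mark.parametrize(
        "supported, fraction, bin_label",
        [("all", 1.0, "100%"), ("none", 0.0, "0-20%")],
    )
    def test_extremes(self, supported, fraction, bin_label):
        members = {"A", "B", "C", "D"}
        pairs = {frozenset(p) for p in itertools.combinations(sorted(members), 2)}
        rep = support_fraction(members, pairs if supported == "all" else set())
        assert rep.fraction == fraction
        assert rep.bin == bin_label

    def test_singleton_rejected_and_skipped_in_report(self):
        with pytest.raises(ValueError):
            support_fraction({"A"}, set())
        report = support_report([{"A"}, {"B", "C"}], {frozenset("BC")})
        assert list(report["n_genes"]) == [2]

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        for _ in range(100):
            size = rng.integers(2, 9)
            members = set(rng.choice(genes, size=size, replace=False))
            supported = set()
            for a, b in itertools.combinations(sorted(genes), 2):
                if rng.random() < 0.4:
                    supported.add(frozenset((a, b)))
            # brute-force oracle: nested loop over unordered pairs
            n_hit = 0
            n_tot = 0
            mem = sorted(members)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    n_tot += 1
                    if frozenset((mem[i], mem[j])) in supported:
                        n_hit += 1
            rep = support_fraction(members, supported)
            assert (rep.n_pairs, rep.n_supported) == (n_tot, n_hit)


class TestRoleSetJaccard:
    def _roles(self, mapping):
        rows = [(g, r, ss) for g, items in mapping.items() for r, ss in items]
        return RoleMap(pd.DataFrame(rows, columns=list(RoleMap.COLUMNS)))

    def test_shared_role_overlap(self):
        # Re = {r1,r2,r3}, Rx = {r2,r3,r4}, all four roles occur in both
        # genomes -> |int| = 2, |union| = 4
        roles_a = self._roles({
            "a1": [("r1", "s"), ("r2", "s"), ("r3", "s")],
            "a2": [("r4", "s")],
        })
        roles_b = self._roles({
            "b1": [("r2", "s"), ("r3", "s"), ("r4", "s")],
            "b2": [("r1", "s")],
        })
        assert role_set_jaccard({"a1"}, {"b1"}, roles_a, roles_b) == pytest.approx(0.5)

    def test_identical_and_disjoint_role_sets(self):
        roles_a = self._roles({"a1": [("r1", "s"), ("r2", "s")], "a2": [("r3", "s")]})
        roles_b = self._roles({"b1": [("r1", "s"), ("r2", "s")], "b2": [("r3", "s")]})
        assert role_set_jaccard({"a1"}, {"b1"}, roles_a, roles_b) == 1.0
        assert role_set_jaccard({"a1"}, {"b2"}, roles_a, roles_b) == 0.0

    def test_no_shared_roles_skipped(self):
        roles_a = self._roles({"a1": [("only-in-a", "s")]})
        roles_b = self._roles({"b1": [("only-in-b", "s")]})
        with pytest.warns(UserWarning, match="skipped"):
            assert role_set_jaccard({"a1"}, {"b1"}, roles_a, roles_b) is None


class TestResampling:
    def test_full_fraction_equals_full_run(self, default_dataset):
        expr, features, roles, truth = default_dataset
        table = subsample_sensitivity(
            expr, features, roles, truth.always_on, fractions=[1.0], reps=2, seed=0
        )
        full = infer_atomic_regulons(expr, features, roles, truth.always_on).summary()
        for _, row in table.iterrows():
            assert {k: row[k] for k in full} == full

    def test_fixed_seed_reproducible(self, default_dataset):
        expr, features, roles, truth = default_dataset
        kw = dict(fractions=[0.2], reps=3, seed=11)
        t1 = subsample_sensitivity(expr, features, roles, truth.always_on, **kw)
        t2 = subsample_sensitivity(expr, features, roles, truth.always_on, **kw)
        assert t1.equals(t2)

    def test_tiny_fraction_skipped_with_warning(self, default_dataset):
        expr, features, roles, truth = default_dataset
        with pytest.warns(UserWarning, match="skipped"):
            table = subsample_sensitivity(
                expr, features, roles, truth.always_on, fractions=[0.001], reps=1, seed=0
            )
        assert table.empty

    def test_crossval_identical_halves_agree_perfectly(self, default_dataset):
        expr, features, roles, truth = default_dataset
        # duplicate the first 10 experiments under new names: the two halves
        # carry identical data, so each AR finds an exact counterpart
        left = expr.data.iloc[:, :10]
        right = left.copy()
        right.columns = [f"dup_{c}" for c in right.columns]
        doubled = ExpressionMatrix(pd.concat([left, right], axis=1))
        table = crossval_jaccard(
            doubled, features, roles, truth.always_on,
            split=(list(left.columns), list(right.columns)),
        )
        assert table.mean.loc["Set1", "Set2"] == pytest.approx(1.0)
        assert table.mean.loc["Set2", "Set1"] == pytest.approx(1.0)
        assert (np.diag(table.mean) == 1.0).all()

    def test_crossval_reproducible_under_seed(self, default_dataset):
        expr, features, roles, truth = default_dataset
        sub = ExpressionMatrix(expr.data.iloc[:, :20].copy())
        t1 = crossval_jaccard(sub, features, roles, truth.always_on, seed=5)
        t2 = crossval_jaccard(sub, features, roles, truth.always_on, seed=5)
        assert t1.mean.equals(t2.mean) and t1.sd.equals(t2.sd)
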