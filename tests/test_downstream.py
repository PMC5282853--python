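import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from emdn import downstream
from emdn.downstream import (
    Eigengene,
    activity_scores,
    correlation_calls,
    eigengene,
    fisher_exact_2x2,
    hypergeometric_enrichment,
    logrank_test,
    module_recovery_metrics,
    nmi,
    partition_from_modules,
    prognostic_index,
    split_risk_groups,
)
from emdn.netio import ClinicalTable, Module, OmicsMatrix, ValidationError


def omics(arr, genes=None, layer="expression"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return OmicsMatrix(
        data=pd.DataFrame(arr, index=genes,
                          columns=[f"s{j}" for j in range(arr.shape[1])]),
        layer_tag=layer,
    )


class TestEigengene:
    def test_rank_one_recovers_shared_profile(self):
        u = np.array([1.0, 3.0, 2.0, 5.0])
        X = np.vstack([2 * u, u, 3 * u])
        eig = eigengene(omics(X), {"g0", "g1", "g2"})
        expect = u / np.linalg.norm(u)
        assert eig.values.to_numpy() == pytest.approx(expect, abs=1e-10)

    def test_constant_submatrix_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            eigengene(omics(np.full((3, 4), 0.5)), {"g0", "g1", "g2"})

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            eigengene(omics(np.eye(2)), {"g0", "g1"})

    def test_unit_norm_and_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 12))
        m = omics(X)
        a = eigengene(m, ["g0", "g1", "g2", "g3"])
        b = eigengene(m, ["g3", "g1", "g0", "g2"])
        assert np.linalg.norm(a.values) == pytest.approx(1.0)
        assert a.values.to_numpy() == pytest.approx(b.values.to_numpy())

    def test_sign_convention_nonneg_corr_with_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 10)) + 3 * rng.normal(size=10)
        eig = eigengene(omics(X), [f"g{i}" for i in range(4)])
        mean = X.mean(axis=0)
        assert np.corrcoef(eig.values, mean)[0, 1] >= 0


class TestCorrelationCalls:
    def eig(self, v, mid="m"):
        v = np.asarray(v, dtype=float)
        v = v / np.linalg.norm(v)
        return Eigengene(module_id=mid,
                         values=pd.Series(v, index=[f"s{i}" for i in range(len(v))]))

    def test_identical_eigengenes_positive(self):
        v = np.array([0.1, 0.5, -0.3, 0.7, 0.2])
        calls = correlation_calls([(self.eig(v), self.eig(v))])
        assert calls[0].pearson_r == pytest.approx(1.0)
        assert calls[0].call == "positive"

    def test_negated_eigengene_negative(self):
        v = np.array([0.1, 0.5, -0.3, 0.7, 0.2])
        calls = correlation_calls([(self.eig(v), self.eig(-v))])
        assert calls[0].pearson_r == pytest.approx(-1.0)
        assert calls[0].call == "negative"

    def test_independent_vectors_called_none(self):
        rng = np.random.default_rng(123)
        pairs = [
            (self.eig(rng.normal(size=100), f"m{i}"),
             self.eig(rng.normal(size=100), f"m{i}"))
            for i in range(5)
        ]
        calls = correlation_calls(pairs)
        assert all(abs(c.pearson_r) < 0.3 for c in calls)
        assert all(c.call == "none" for c in calls)

    def test_flip_invariance_of_magnitude(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(size=20)
        c1 = correlation_calls([(self.eig(a), self.eig(b))])[0]
        c2 = correlation_calls([(self.eig(-a), self.eig(b))])[0]
        assert abs(c1.pearson_r) == pytest.approx(abs(c2.pearson_r))


class TestActivityAndPrognosis:
    def module(self, genes, name="m1"):
        return Module(genes=frozenset(genes), name=name)

    def test_sqrt_normalization_worked_example(self):
        m = omics(np.full((4, 3), 0.5), layer="methylation")
        feats = activity_scores(m, [self.module([f"g{i}" for i in range(4)])])
        assert feats.loc["m1"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_mean_normalization(self):
        m = omics(np.full((4, 3), 0.5), layer="methylation")
        feats = activity_scores(
            m, [self.module([f"g{i}" for i in range(4)])], normalization="mean"
        )
        assert feats.loc["m1"].tolist() == pytest.approx([0.5, 0.5, 0.5])

    def test_single_gene_module_both_modes(self):
        m = omics([[0.3, 0.6]], layer="methylation")
        for mode in ("sqrt", "mean"):
            feats = activity_scores(m, [self.module(["g0"])], normalization=mode)
            assert feats.loc["m1"].tolist() == pytest.approx([0.3, 0.6])

    def test_absent_gene_warns_and_adjusts(self):
        m = omics([[0.4, 0.4]], layer="methylation")
        with pytest.warns(UserWarning, match="absent"):
            feats = activity_scores(
                m, [self.module(["g0", "zz"])], normalization="mean"
            )
        assert feats.loc["m1"].tolist() == pytest.approx([0.4, 0.4])

    def test_prognostic_index_hand_example(self):
        means = pd.DataFrame([[0.2, 0.6], [0.5, 0.1]],
                             index=["m1", "m2"], columns=["p1", "p2"])
        idx = prognostic_index(np.array([1.0, -1.0]), means)
        assert idx["p1"] == pytest.approx(-0.3)
        assert idx["p2"] == pytest.approx(0.5)

    def test_single_module_unit_beta_identity(self):
        means = pd.DataFrame([[0.2, 0.6, 0.4]], index=["m1"],
                             columns=["p1", "p2", "p3"])
        idx = prognostic_index(np.array([1.0]), means)
        assert idx.tolist() == pytest.approx([0.2, 0.6, 0.4])

    def test_median_split_and_degenerate(self):
        idx = pd.Series([0.1, 0.9, 0.5, 0.7], index=list("abcd"))
        groups = split_risk_groups(idx)
        assert groups.tolist() == ["low", "high", "low", "high"]
        flat = split_risk_groups(pd.Series(np.zeros(4), index=list("abcd")))
        assert (flat == "low").all()


class TestLogrank:
    def clinical(self, times, events, ids=None):
        ids = ids or [f"p{i}" for i in range(len(times))]
        return ClinicalTable(
            table=pd.DataFrame({"time": times, "event": events}, index=ids)
        )

    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 1, 0, 1] * 2
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"p{i}" for i in range(8)])
        stat, p = logrank_test(groups, self.clinical(times, events))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        times = [1.0] * 20 + [10.0] * 20
        events = [1] * 40
        groups = pd.Series(["a"] * 20 + ["b"] * 20,
                           index=[f"p{i}" for i in range(40)])
        stat, p = logrank_test(groups, self.clinical(times, events))
        assert p < 0.01

    def test_km_curves_start_at_one_and_decrease(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"p{i}" for i in range(8)])
        curves = downstream.km_curves(groups, self.clinical(times, events))
        for _, sub in curves.groupby("group"):
            s = sub.sort_values("time")["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_all_censored_rejected(self):
        groups = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        clin = self.clinical([1, 2, 3, 4], [0, 0, 0, 0], ids=list("wxyz"))
        with pytest.raises(ValidationError, match="censored"):
            logrank_test(groups, clin)

    def test_label_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5.0, size=30)
        events = rng.integers(0, 2, size=30)
        events[0] = 1
        ids = [f"p{i}" for i in range(30)]
        clin = self.clinical(times.tolist(), events.tolist(), ids=ids)
        ps = []
        for _ in range(100):
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            ps.append(logrank_test(pd.Series(labels, index=ids), clin)[1])
        ps = np.asarray(ps)
        # under the null, p-values should spread over (0,1)
        assert 0.2 < np.mean(ps) < 0.8
        assert (ps < 0.5).sum() > 20 and (ps > 0.5).sum() > 20


class TestEnrichmentAndFisher:
    def test_disjoint_set_p_one(self):
        out = hypergeometric_enrichment(
            {"a", "b"}, {"s": {"x", "y"}}, {"a", "b", "x", "y", "z"}
        )
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_subset_matches_bruteforce_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        module = set(universe[:5])
        gene_set = set(universe[:10])
        out = hypergeometric_enrichment(module, {"s": gene_set}, universe)
        # brute force: P(overlap >= 5) when drawing 5 from 100 with 10 marked
        total = math.comb(100, 5)
        expect = sum(
            math.comb(10, k) * math.comb(90, 5 - k) for k in range(5, 6)
        ) / total
        assert out.loc["s", "p"] == pytest.approx(expect, rel=1e-10)

    def test_bh_at_least_raw(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(50)]
        module = set(rng.choice(universe, 8, replace=False))
        sets = {
            f"s{j}": set(rng.choice(universe, 12, replace=False)) for j in range(6)
        }
        out = hypergeometric_enrichment(module, sets, universe)
        assert (out["adjusted_p"] >= out["p"] - 1e-12).all()

    def test_fisher_survival_worked_example(self):
        # 7 of 26 modules vs 112 of 1107 random modules survival-associated
        p = fisher_exact_2x2(7, 19, 112, 995, alternative="greater")
        assert p == pytest.approx(1.4e-2, rel=0.05)

    def test_proportional_rows_p_one_greater(self):
        assert fisher_exact_2x2(5, 10, 10, 20, alternative="greater") > 0.5

    def test_two_sided_matches_enumeration(self):
        # enumerate all tables with the margins of (3,1;1,3)
        a, b, c, d = 3, 1, 1, 3
        row1, col1, n = a + b, a + c, a + b + c + d
        probs = {}
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            probs[x] = (
                math.comb(col1, x)
                * math.comb(n - col1, row1 - x)
                / math.comb(n, row1)
            )
        p_obs = probs[a]
        expect = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(expect, rel=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestNMI:
    def test_identity_is_one(self):
        P = [{1, 2}, {3, 4}, {5}]
        assert nmi(P, P) == pytest.approx(1.0)

    def test_crosscutting_blocks_zero(self):
        P = [{1, 2}, {3, 4}]
        Q = [{1, 3}, {2, 4}]  # confusion matrix all ones
        assert nmi(P, Q) == pytest.approx(0.0, abs=1e-12)

    def test_single_block_conventions(self):
        assert nmi([{1, 2, 3}], [{1, 2, 3}]) == 1.0
        assert nmi([{1, 2, 3}], [{1}, {2, 3}]) == 0.0

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError):
            nmi([{1, 2}], [{1, 3}])

    def test_agrees_with_sklearn_arithmetic_normalization(self):
        rng = np.random.default_rng(0)
        labels_a = rng.integers(0, 4, size=60)
        labels_b = rng.integers(0, 3, size=60)
        ours = nmi(
            {i: int(l) for i, l in enumerate(labels_a)},
            {i: int(l) for i, l in enumerate(labels_b)},
        )
        ref = normalized_mutual_info_score(
            labels_a, labels_b, average_method="arithmetic"
        )
        assert ours == pytest.approx(ref, abs=1e-10)

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=40)
    def test_symmetry_and_range(self, labels):
        rng = np.random.default_rng(7)
        other = rng.integers(0, 3, size=len(labels))
        P = {i: l for i, l in enumerate(labels)}
        Q = {i: int(l) for i, l in enumerate(other)}
        a, b = nmi(P, Q), nmi(Q, P)
        assert a == pytest.approx(b)
        assert -1e-12 <= a <= 1 + 1e-12


class TestPartitionFromModules:
    def test_covering_modules_and_leftover_block(self):
        mods = [Module(genes=frozenset({1, 2, 3}), H=0.1),
                Module(genes=frozenset({3, 4}), H=0.5)]
        blocks = partition_from_modules(mods, {1, 2, 3, 4, 5, 6})
        # 3 goes to the tighter module; 5,6 form one leftover block
        assert {frozenset(b) for b in blocks} == {
            frozenset({1, 2, 3}), frozenset({4}), frozenset({5, 6})
        }


class TestRecoveryMetrics:
    def test_table_style_partial_recovery(self):
        truth = set(range(11))
        found = set(range(6)) | {100, 101}  # 6 true positives of 8
        acc, fpr, ppv, fdr = module_recovery_metrics(found, truth, n_genes=7000)
        assert acc == pytest.approx(6 / 11)
        assert ppv == pytest.approx(0.75)
        assert fdr == pytest.approx(0.25)
        assert fpr == pytest.approx(2 / 6989)

    def test_perfect_recovery(self):
        truth = set(range(10))
        acc, fpr, ppv, fdr = module_recovery_metrics(truth, truth, 100)
        assert (acc, fpr, ppv, fdr) == (1.0, 0.0, 1.0, 0.0)

    def test_disjoint_found(self):
        acc, fpr, ppv, fdr = module_recovery_metrics(
            {100, 101, 102}, set(range(10)), 100
        )
        assert acc == 0.0 and ppv == 0.0 and fdr == 1.0
        assert fpr == pytest.approx(3 / 90)

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_counts_are_integers(self, data):
        universe = list(range(50))
        truth = set(data.draw(st.sets(st.sampled_from(universe), min_size=1,
                                      max_size=20)))
        found = set(data.draw(st.sets(st.sampled_from(universe), max_size=20)))
        acc, fpr, ppv, fdr = module_recovery_metrics(found, truth, 60)
        assert (acc * len(truth)) == pytest.approx(round(acc * len(truth)))
        if found:
            assert (ppv * len(found)) == pytest.approx(round(ppv * len(found)))
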