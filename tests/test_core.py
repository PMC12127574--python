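"""Unit and property tests for the scoring pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bges import (
    AlignmentError,
    BinaryMatrix,
    ConfigurationError,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    binarize,
    compute_reference_stats,
    enrich,
    fold_change_of_means,
    one_vs_rest_scores,
    score_gene_sets,
)
from conftest import oracle_binary, oracle_scores, random_instance


class TestReferenceStats:
    def test_population_divisor(self):
        """mu and sigma over C2 use the 1/n population formula: {2,4,6} -> sigma=sqrt(8/3)."""
        values = pd.DataFrame(
            {"r1": [2.0], "r2": [4.0], "r3": [6.0], "q1": [9.0]}, index=["g"]
        )
        labels = pd.Series(["C2", "C2", "C2", "C1"], index=values.columns)
        stats = compute_reference_stats(ExpressionMatrix(values, labels, "C2"))
        assert stats.mu["g"] == 4.0
        assert stats.sigma["g"] == pytest.approx(math.sqrt(8.0 / 3.0))
        assert stats.n_ref == 3

    def test_constant_reference_gives_zero_sigma(self):
        values = pd.DataFrame(
            {"r1": [5.0], "r2": [5.0], "r3": [5.0], "r4": [5.0], "q1": [9.0]},
            index=["g"],
        )
        labels = pd.Series(["C2"] * 4 + ["C1"], index=values.columns)
        stats = compute_reference_stats(ExpressionMatrix(values, labels, "C2"))
        assert stats.mu["g"] == 5.0
        assert stats.sigma["g"] == 0.0

    def test_single_reference_sample(self):
        values = pd.DataFrame({"r1": [7.0], "q1": [9.0]}, index=["g"])
        labels = pd.Series(["C2", "C1"], index=values.columns)
        stats = compute_reference_stats(ExpressionMatrix(values, labels, "C2"))
        assert stats.mu["g"] == 7.0 and stats.sigma["g"] == 0.0

    def test_no_reference_samples_rejected(self, toy_values, toy_labels):
        with pytest.raises(ConfigurationError):
            ExpressionMatrix(toy_values, toy_labels, reference_level="missing_level")

    def test_non_finite_values_rejected(self, toy_values, toy_labels):
        bad = toy_values.copy()
        bad.loc["g2", "t1"] = np.nan
        with pytest.raises(DataError, match="g2"):
            ExpressionMatrix(bad, toy_labels, "normal")


class TestBinarize:
    def test_strict_threshold(self):
        """v=6 vs threshold 4+sqrt(8/3)=5.633 -> 1; a tie at the threshold -> 0."""
        values = pd.DataFrame(
            {"r1": [2.0, 5.0], "r2": [4.0, 5.0], "r3": [6.0, 5.0], "q1": [6.0, 5.0]},
            index=["ga", "gb"],
        )
        labels = pd.Series(["C2"] * 3 + ["C1"], index=values.columns)
        expr = ExpressionMatrix(values, labels, "C2")
        binary = binarize(expr, compute_reference_stats(expr))
        assert binary.entries.loc["ga", "q1"] == 1  # 6 > 5.633
        assert binary.entries.loc["gb", "q1"] == 0  # 5 > 5 is false

    def test_shift_invariance_of_threshold(self, toy_expr):
        """Adding a constant to one gene in all samples leaves the binary matrix unchanged."""
        stats = compute_reference_stats(toy_expr)
        base = binarize(toy_expr, stats)
        shifted_values = toy_expr.values.copy()
        shifted_values.loc["g1"] += 13.5
        shifted = ExpressionMatrix(shifted_values, toy_expr.labels, "normal")
        again = binarize(shifted, compute_reference_stats(shifted))
        pd.testing.assert_frame_equal(base.entries, again.entries)

    def test_gene_mismatch_rejected(self, toy_expr):
        stats = compute_reference_stats(toy_expr)
        other = ExpressionMatrix(
            toy_expr.values.rename(index={"g1": "gZ"}), toy_expr.labels, "normal"
        )
        with pytest.raises(AlignmentError):
            binarize(other, stats)

    def test_which_all_scores_reference_samples_too(self, toy_expr):
        stats = compute_reference_stats(toy_expr)
        allb = binarize(toy_expr, stats, which="all")
        assert list(allb.sample_ids) == list(toy_expr.sample_ids)


class TestScoreGeneSets:
    def test_counting(self):
        binary = BinaryMatrix(
            pd.DataFrame({"s": [1, 1, 0, 1]}, index=["a", "b", "c", "d"])
        )
        em = score_gene_sets(binary, GeneSetCollection({"S": ["a", "b", "c", "d"]}))
        assert em.scores.loc["S", "s"] == 0.75

    def test_extreme_columns(self):
        binary = BinaryMatrix(
            pd.DataFrame({"hot": [1, 1, 1], "cold": [0, 0, 0]}, index=["a", "b", "c"])
        )
        em = score_gene_sets(binary, GeneSetCollection({"S": ["a", "b", "c"]}))
        assert em.scores.loc["S", "hot"] == 1.0
        assert em.scores.loc["S", "cold"] == 0.0

    def test_denominator_modes(self):
        """5-gene set, 4 measured, hits (1,1,0,1): measured -> 3/4, full -> 3/5."""
        binary = BinaryMatrix(
            pd.DataFrame({"s": [1, 1, 0, 1]}, index=["a", "b", "c", "d"])
        )
        sets = GeneSetCollection({"S": ["a", "b", "c", "d", "ghost"]})
        assert score_gene_sets(binary, sets, "measured").scores.loc["S", "s"] == 0.75
        em_full = score_gene_sets(binary, sets, "full")
        assert em_full.scores.loc["S", "s"] == pytest.approx(3 / 5)
        assert em_full.genes_measured["S"] == 4

    def test_unmeasured_set_dropped_with_warning(self):
        binary = BinaryMatrix(pd.DataFrame({"s": [1]}, index=["a"]))
        sets = GeneSetCollection({"ok": ["a"], "ghostly": ["x", "y"]})
        with pytest.warns(UserWarning, match="dropped"):
            em = score_gene_sets(binary, sets)
        assert em.dropped_sets == ["ghostly"]
        assert list(em.scores.index) == ["ok"]

    def test_all_sets_unmeasured_is_error(self):
        binary = BinaryMatrix(pd.DataFrame({"s": [1]}, index=["a"]))
        with pytest.warns(UserWarning):
            with pytest.raises(DataError):
                score_gene_sets(binary, GeneSetCollection({"g": ["x"]}))


class TestEndToEnd:
    def test_toy_matches_oracle_exactly(self, toy_values, toy_labels, toy_sets):
        em = enrich(
            ExpressionMatrix(toy_values, toy_labels, "normal"),
            GeneSetCollection(toy_sets),
        )
        expected = oracle_scores(toy_values, toy_labels, "normal", toy_sets)
        pd.testing.assert_frame_equal(
            em.scores, expected, check_names=False, check_dtype=False
        )

    def test_oracle_equivalence_on_random_instances(self):
        """Vectorized pipeline == naive triple loop, exactly, on 50 random instances."""
        rng = np.random.default_rng(20240917)
        for _ in range(50):
            values, labels, sets = random_instance(rng)
            mode = "measured" if rng.random() < 0.5 else "full"
            expr = ExpressionMatrix(values, labels, "C2")
            binary = binarize(expr, compute_reference_stats(expr))
            assert binary.entries.astype(int).equals(
                oracle_binary(values, labels, "C2")
            )
            em = enrich(expr, GeneSetCollection(sets), denominator_mode=mode)
            expected = oracle_scores(values, labels, "C2", sets, denominator_mode=mode)
            assert (em.scores - expected.loc[em.scores.index]).abs().to_numpy().max() == 0.0

    def test_query_duplicating_reference(self):
        """When C1 duplicates C2, each ES equals the fraction of set genes above their own mu+sigma."""
        rng = np.random.default_rng(5)
        ref = pd.DataFrame(
            rng.gamma(2, 3, size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"r{i}" for i in range(4)],
        )
        dup = ref.copy()
        dup.columns = [f"q{i}" for i in range(4)]
        values = pd.concat([ref, dup], axis=1)
        labels = pd.Series(["C2"] * 4 + ["C1"] * 4, index=values.columns)
        members = ["g0", "g1", "g2", "g3", "g4"]
        em = enrich(
            ExpressionMatrix(values, labels, "C2"), GeneSetCollection({"S": members})
        )
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=0)
        for j in range(4):
            frac = sum(ref.loc[g].iloc[j] > mu[g] + sd[g] for g in members) / len(members)
            assert em.scores.loc["S", f"q{j}"] == frac

    def test_scale_equivariance(self):
        """Per-gene positive rescaling of all samples leaves scores unchanged."""
        rng = np.random.default_rng(11)
        values, labels, sets = random_instance(rng)
        base = enrich(ExpressionMatrix(values, labels, "C2"), GeneSetCollection(sets))
        scale = pd.Series(rng.uniform(0.5, 20, len(values)), index=values.index)
        rescaled = values.mul(scale, axis=0)
        again = enrich(ExpressionMatrix(rescaled, labels, "C2"), GeneSetCollection(sets))
        pd.testing.assert_frame_equal(base.scores, again.scores)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(-50, 50, allow_nan=False))
    def test_per_gene_shift_invariance_property(self, seed, shift):
        """Adding any constant to one gene across ALL samples never changes scores."""
        rng = np.random.default_rng(seed)
        values, labels, sets = random_instance(rng, max_genes=10, max_samples=8, max_sets=3)
        gene = values.index[rng.integers(len(values))]
        base = enrich(ExpressionMatrix(values, labels, "C2"), GeneSetCollection(sets))
        shifted = values.copy()
        shifted.loc[gene] += shift
        again = enrich(ExpressionMatrix(shifted, labels, "C2"), GeneSetCollection(sets))
        pd.testing.assert_frame_equal(base.scores, again.scores)

    def test_monotone_in_single_entry(self):
        """Raising one C1 entry never lowers the score of sets containing that gene."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            values, labels, sets = random_instance(rng, max_genes=12, max_samples=8)
            expr = ExpressionMatrix(values, labels, "C2")
            base = enrich(expr, GeneSetCollection(sets))
            q = expr.query_samples[0]
            gene = values.index[rng.integers(len(values))]
            bumped = values.copy()
            bumped.loc[gene, q] += rng.uniform(0.1, 30)
            em2 = enrich(
                ExpressionMatrix(bumped, labels, "C2"), GeneSetCollection(sets)
            )
            for name in base.scores.index:
                if gene in sets[name]:
                    assert em2.scores.loc[name, q] >= base.scores.loc[name, q]
                else:
                    assert em2.scores.loc[name, q] == base.scores.loc[name, q]

    def test_sample_and_gene_permutation(self):
        """Permuting samples permutes columns identically; permuting genes is a no-op."""
        rng = np.random.default_rng(21)
        values, labels, sets = random_instance(rng)
        base = enrich(ExpressionMatrix(values, labels, "C2"), GeneSetCollection(sets))
        cols = list(rng.permutation(values.columns))
        perm = enrich(
            ExpressionMatrix(values[cols], labels[cols], "C2"), GeneSetCollection(sets)
        )
        pd.testing.assert_frame_equal(
            base.scores[perm.scores.columns], perm.scores
        )
        rows = list(rng.permutation(values.index))
        gperm = enrich(
            ExpressionMatrix(values.loc[rows], labels, "C2"), GeneSetCollection(sets)
        )
        pd.testing.assert_frame_equal(base.scores, gperm.scores)

    def test_scores_are_multiples_of_unit_fraction(self):
        rng = np.random.default_rng(8)
        values, labels, sets = random_instance(rng)
        em = enrich(ExpressionMatrix(values, labels, "C2"), GeneSetCollection(sets))
        for name in em.scores.index:
            denom = em.genes_measured[name]
            ks = em.scores.loc[name].to_numpy() * denom
            assert np.allclose(ks, np.round(ks))
            assert em.scores.loc[name].between(0, 1).all()


class TestOneVsRest:
    def test_perfect_separation(self):
        """Signature genes at 10 in their type and ~0 elsewhere give ES 1 vs 0."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(6)]
        cells = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=cells)
        vals = pd.DataFrame(
            rng.uniform(0, 0.01, size=(6, 8)), index=genes, columns=cells
        )
        vals.loc[["g0", "g1"]] = 0.0  # signature silent outside type A
        vals.loc[["g0", "g1"], ["a0", "a1", "a2", "a3"]] = 10.0
        em = one_vs_rest_scores(
            ExpressionMatrix(vals, labels), GeneSetCollection({"A": ["g0", "g1"]})
        )
        assert (em.scores.loc["A", ["a0", "a1", "a2", "a3"]] == 1.0).all()
        assert (em.scores.loc["A", ["b0", "b1", "b2", "b3"]] == 0.0).all()

    def test_matches_per_type_brute_force(self):
        """9-cell, 6-gene, 3-type instance equals per-type oracle recomputation."""
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(6)]
        cells = [f"c{i}" for i in range(9)]
        vals = pd.DataFrame(
            rng.gamma(2, 3, size=(6, 9)), index=genes, columns=cells
        )
        labels = pd.Series(["A", "A", "A", "B", "B", "B", "C", "C", "C"], index=cells)
        sigs = {
            "A": ["g0", "g1"],
            "B": ["g2", "g3"],
            "C": ["g4", "g5"],
        }
        em = one_vs_rest_scores(ExpressionMatrix(vals, labels), GeneSetCollection(sigs))
        for t in ["A", "B", "C"]:
            rest_labels = labels.where(labels == t, "rest")
            expected = oracle_scores(
                vals, rest_labels, "rest", {t: sigs[t]}, which="all"
            )
            assert (em.scores.loc[t] - expected.loc[t]).abs().max() == 0.0

    def test_single_type_rejected(self):
        vals = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["c1", "c2"])
        labels = pd.Series(["A", "A"], index=["c1", "c2"])
        with pytest.raises(ConfigurationError):
            one_vs_rest_scores(
                ExpressionMatrix(vals, labels), GeneSetCollection({"A": ["g"]})
            )


class TestFoldChange:
    def test_hand_computed_ratio(self):
        scores = [0.8, 0.6, 0.2, 0.3, 0.2]
        mask = [True, True, False, False, False]
        assert fold_change_of_means(scores, mask) == pytest.approx(0.7 / (0.7 / 3))

    def test_identical_groups(self):
        assert fold_change_of_means([0.4, 0.4, 0.4, 0.4], [True, True, False, False]) == 1.0

    def test_zero_out_group_conventions(self):
        assert fold_change_of_means([0.5, 0.5, 0.0], [True, True, False]) == math.inf
        assert fold_change_of_means([0.0, 0.0, 0.0], [True, False, False]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            fold_change_of_means([0.1, 0.2], [True, True])
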