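import numpy as np
import pytest

from smallrna.core_io import CountTable
from smallrna.countstats import CorrectionFactor
from smallrna.diffexp import (
    DEParams,
    adjust_pvalues,
    differential_expression,
    fisher_test,
    hierarchical_cluster,
    pca,
    quantile_normalize,
)
from smallrna.simulate import SimProfile, pick_condition_effects, simulate_count_table
from oracles import bh_oracle, fisher_two_sided_oracle


def _table(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return CountTable(
        features=[(f"f{i}", "miRNA") for i in range(rows.shape[0])],
        samples=samples or [f"s{j}" for j in range(rows.shape[1])],
        counts=rows,
    )


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        t = quantile_normalize(_table([[1, 2], [2, 4], [3, 6]]))
        expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
        assert np.allclose(t.counts, expected)

    def test_identical_columns_unchanged(self):
        t0 = _table([[3, 3], [1, 1], [9, 9]])
        assert np.allclose(quantile_normalize(t0).counts, t0.counts)

    def test_constant_column_gets_mean_over_ranks(self):
        t = quantile_normalize(_table([[5, 1], [5, 2], [5, 3]]))
        # sorted rank means: (5+1)/2, (5+2)/2, (5+3)/2 -> constant col all ties
        assert np.allclose(t.counts[:, 0], np.mean([3.0, 3.5, 4.0]))
        assert np.allclose(t.counts[:, 1], [3.0, 3.5, 4.0])

    def test_columns_share_value_multiset_and_grand_mean(self):
        rng = np.random.default_rng(0)
        x = rng.random(size=(50, 4)) * 1000  # continuous: tie-free columns
        t = quantile_normalize(_table(x))
        cols = [np.sort(t.counts[:, j]) for j in range(4)]
        for c in cols[1:]:
            assert np.allclose(cols[0], c)
        assert np.isclose(t.counts.mean(), x.mean())

    def test_single_sample_identity_with_warning(self):
        t0 = _table([[1], [5]])
        with pytest.warns(UserWarning):
            t = quantile_normalize(t0)
        assert np.allclose(t.counts, t0.counts)


class TestFisher:
    def test_empty_margin_gives_p_one(self):
        assert fisher_test(0, 0, 100, 100) == 1.0

    def test_symmetric_table_gives_p_one(self):
        assert fisher_test(5, 5, 100, 100) == 1.0

    def test_two_sided_symmetry_under_swap(self):
        p1 = fisher_test(10, 3, 500, 800)
        p2 = fisher_test(3, 10, 800, 500)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p equals exact-rational enumeration of all tables with
        the observed margins (e.g. 16 tables for a+b=15)."""
        assert fisher_test(10, 5, 1000, 1000) == pytest.approx(
            fisher_two_sided_oracle(10, 5, 1000, 1000), abs=1e-12
        )
        rng = np.random.default_rng(123)
        for _ in range(200):
            n1 = int(rng.integers(10, 150))
            n2 = int(rng.integers(10, 150))
            a = int(rng.integers(0, min(20, n1) + 1))
            b = int(rng.integers(0, min(20, n2) + 1))
            assert fisher_test(a, b, n1, n2) == pytest.approx(
                fisher_two_sided_oracle(a, b, n1, n2), abs=1e-12
            ), (a, b, n1, n2)

    def test_invalid_margins_error(self):
        with pytest.raises(ValueError):
            fisher_test(5, 0, 4, 100)
        with pytest.raises(ValueError):
            fisher_test(0, 0, 0, 10)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        assert adjust_pvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        assert adjust_pvalues([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_matches_direct_definition(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        assert adjust_pvalues(p) == pytest.approx(bh_oracle(list(p)))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(25)
        assert np.all(adjust_pvalues(p) >= p - 1e-15)


class TestDifferentialExpression:
    def test_identical_columns_all_unchanged(self):
        t = _table([[50, 50], [200, 200], [5, 5]], ["A", "B"])
        records, summary = differential_expression(t, "A", "B")
        assert all(r.call == "unchanged" for r in records)
        assert all(r.signed_fc == 1.0 for r in records)
        assert summary.n_up == summary.n_down == 0

    def test_double_zero_feature_unchanged_with_correction(self):
        t = _table([[0, 0], [100, 100]], ["A", "B"])
        params = DEParams(correction=CorrectionFactor(30, "user"))
        records, _ = differential_expression(t, "A", "B", params)
        assert records[0].signed_fc == 1.0 and records[0].call == "unchanged"

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            differential_expression(_table([[1, 2]], ["A", "B"]), "A", "nope")

    def test_call_invariant_to_feature_order(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2000, size=(30, 2)).astype(float)
        t = _table(x, ["A", "B"])
        records, _ = differential_expression(t, "A", "B")
        perm = rng.permutation(30)
        t2 = CountTable(
            features=[t.features[i] for i in perm], samples=["A", "B"], counts=x[perm]
        )
        records2, _ = differential_expression(t2, "A", "B")
        by_id = {r.feature_id: (r.call, r.p_value) for r in records}
        assert all(by_id[r.feature_id] == (r.call, r.p_value) for r in records2)

    def test_recovers_simulated_fold_changes(self):
        """With deep counts and 4-fold perturbations on 10% of miRNAs, the
        Fisher path calls nearly all perturbed features while the joint
        p + fold-change criterion keeps false calls among nulls below the
        nominal rate."""
        from smallrna.simulate import simulate_abundances, simulate_references

        profile = SimProfile(rng_seed=5, n_reads=200_000)
        libraries = simulate_references(profile)
        abundances = simulate_abundances(profile, libraries)
        effects = pick_condition_effects(profile, libraries["miRNA"], 0.1, 4.0)
        table = simulate_count_table(profile, libraries, abundances, effects)
        records, _ = differential_expression(table, "test", "control")
        perturbed = set(effects)
        called = {r.feature_id for r in records if r.call != "unchanged"}
        assert len(called & perturbed) / len(perturbed) >= 0.9
        nulls = [r for r in records if r.feature_id not in perturbed]
        false_calls = sum(1 for r in nulls if r.call != "unchanged")
        assert false_calls <= 0.05 * len(nulls)


class TestClusteringAndPCA:
    def test_identical_samples_merge_at_zero(self):
        t = _table([[1, 1], [5, 5], [9, 9]], ["A", "B"])
        z, leaves, d = hierarchical_cluster(t)
        assert z[0, 2] == pytest.approx(0.0)
        assert set(leaves) == {"A", "B"}

    def test_anticorrelated_samples_distance_two(self):
        t = _table([[1, 3], [2, 2], [3, 1]], ["A", "B"])
        _, _, d = hierarchical_cluster(t)
        assert d[0, 1] == pytest.approx(2.0)

    def test_two_tight_groups_merge_within_groups_first(self):
        rng = np.random.default_rng(2)
        base1 = rng.integers(10, 1000, size=40).astype(float)
        base2 = rng.permutation(base1)
        cols = [
            base1 + rng.normal(0, 1, 40),
            base1 + rng.normal(0, 1, 40),
            base2 + rng.normal(0, 1, 40),
            base2 + rng.normal(0, 1, 40),
        ]
        t = _table(np.column_stack(cols), ["a1", "a2", "b1", "b2"])
        z, _, _ = hierarchical_cluster(t)
        first_two = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_constant_matrix_zero_variance(self):
        coords, fractions = pca(_table(np.full((10, 3), 4.0)))
        assert np.allclose(fractions, 0)
        assert np.allclose(coords, 0)

    def test_two_samples_single_component(self):
        coords, fractions = pca(_table([[1, 5], [2, 7], [3, 2]]))
        assert fractions.shape == (1,)
        assert fractions[0] == pytest.approx(1.0)

    def test_pc1_separates_simulated_groups(self):
        rng = np.random.default_rng(9)
        base1 = rng.integers(10, 1000, size=50).astype(float)
        base2 = rng.permutation(base1)
        cols = np.column_stack(
            [base1 + rng.normal(0, 5, 50) for _ in range(3)]
            + [base2 + rng.normal(0, 5, 50) for _ in range(3)]
        )
        coords, fractions = pca(_table(cols))
        signs = np.sign(coords[:, 0])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]
        assert fractions.sum() <= 1 + 1e-9
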