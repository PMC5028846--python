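import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from kronfuse import (
    FeatureTable,
    GaussianConfig,
    KronfuseError,
    MutationWeightConfig,
    abs_pearson_similarity,
    combine_max,
    gaussian_similarity,
    mutation_similarity,
    mutation_weights,
    weighted_cosine,
)
from conftest import random_similarity


class TestMutationWeights:
    def test_uniform_all_ones(self):
        w = mutation_weights([0.1, 0.5, 0.9], MutationWeightConfig(weight_scheme="uniform"))
        np.testing.assert_array_equal(w, 1.0)

    def test_zero_sd_fallback(self):
        # constant rates: sigma falls back to 1, so w = exp(-f/h)
        w = mutation_weights([0.1, 0.1, 0.1], MutationWeightConfig(h=10))
        np.testing.assert_allclose(w, np.exp(-0.01))

    def test_empty_errors(self):
        with pytest.raises(KronfuseError):
            mutation_weights([])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_non_increasing_in_frequency(self, freqs):
        w = mutation_weights(np.array(freqs))
        order = np.argsort(freqs)
        assert (np.diff(w[order]) <= 1e-12).all()
        assert ((w > 0) & (w <= 1)).all()


class TestWeightedCosine:
    def test_identical_nonzero_is_one(self):
        assert weighted_cosine([1, 0, 1], [1, 0, 1], [0.3, 9.0, 0.5]) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert weighted_cosine([1, 0], [0, 1], [1, 1]) == 0.0

    def test_half_overlap_uniform(self):
        assert weighted_cosine([1, 1, 0], [1, 0, 1], [1, 1, 1]) == pytest.approx(0.5)

    def test_both_zero_convention(self):
        assert weighted_cosine([0, 0], [0, 0], [1, 1]) == 0.0

    def test_errors(self):
        with pytest.raises(KronfuseError):
            weighted_cosine([1, 0], [1], [1, 1])
        with pytest.raises(KronfuseError):
            weighted_cosine([1, 0], [1, 0], [-1, 1])

    @given(st.integers(0, 2**30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 12)
        z = rng.integers(0, 2, m)
        zp = rng.integers(0, 2, m)
        w = rng.uniform(0.01, 2.0, m)
        assert weighted_cosine(z, zp, w) == pytest.approx(
            oracles.cosine_weighted(z, zp, w), abs=1e-9)


def mut_table(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return FeatureTable(ids, [f"g{j}" for j in range(values.shape[1])], values, "mutation")


class TestMutationSimilarity:
    def test_identical_cells(self):
        sm = mutation_similarity(mut_table([[1, 0, 1], [1, 0, 1]]))
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_elementwise_oracle(self):
        t = mut_table([[1, 1], [0, 1], [0, 0]])
        sm = mutation_similarity(t)
        w = mutation_weights(t.values.mean(axis=0))
        for i in range(3):
            for j in range(3):
                expect = 1.0 if i == j else oracles.cosine_weighted(
                    t.values[i], t.values[j], w)
                assert sm.values[i, j] == pytest.approx(expect, abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 2, (6, 8)).astype(float)
        sm = mutation_similarity(mut_table(vals))
        perm = rng.permutation(6)
        sm_p = mutation_similarity(mut_table(vals[perm], [f"c{i}" for i in perm]))
        np.testing.assert_allclose(sm_p.values, sm.values[np.ix_(perm, perm)], atol=1e-12)

    def test_uniform_weights_equal_plain_cosine(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = rng.integers(0, 2, (10, 8)).astype(float)
            sm = mutation_similarity(mut_table(vals),
                                     MutationWeightConfig(weight_scheme="uniform"))
            for i in range(10):
                for j in range(i + 1, 10):
                    expect = oracles.cosine_weighted(vals[i], vals[j], np.ones(8))
                    assert sm.values[i, j] == pytest.approx(expect, abs=1e-9)


def feat_table(values, tag="copy_number"):
    values = np.asarray(values, dtype=float)
    return FeatureTable([f"c{i}" for i in range(values.shape[0])],
                        [f"f{j}" for j in range(values.shape[1])], values, tag)


class TestGaussianSimilarity:
    def test_two_entities_mean_rule(self):
        # the single pair's squared distance IS the mean -> exp(-1)
        sm = gaussian_similarity(feat_table([[0.0, 0.0], [1.0, 3.0]]))
        assert sm.values[0, 1] == pytest.approx(np.exp(-1))

    def test_fixed_gamma(self):
        cfg = GaussianConfig(bandwidth_rule="fixed", gamma=0.5, standardize=False)
        sm = gaussian_similarity(feat_table([[0.0, 0.0], [1.0, 1.0]]), cfg)
        assert sm.values[0, 1] == pytest.approx(np.exp(-1))

    def test_identical_rows_fixed_gamma(self):
        cfg = GaussianConfig(bandwidth_rule="fixed", gamma=1.0, standardize=False)
        sm = gaussian_similarity(feat_table([[1.0, 2.0], [1.0, 2.0]]), cfg)
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_all_identical_mean_rule_errors(self):
        with pytest.raises(KronfuseError, match="identical"):
            gaussian_similarity(feat_table([[1.0, 2.0], [1.0, 2.0]]))

    def test_matches_oracle_fixed_gamma(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 4))
        cfg = GaussianConfig(bandwidth_rule="fixed", gamma=0.37, standardize=False)
        sm = gaussian_similarity(feat_table(x), cfg)
        np.testing.assert_allclose(sm.values, oracles.gaussian_matrix(x, 0.37), atol=1e-9)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(5, 6))
        sm = gaussian_similarity(feat_table(x))
        sm_p = gaussian_similarity(feat_table(x[:, rng.permutation(6)]))
        np.testing.assert_allclose(sm.values, sm_p.values, atol=1e-9)

    def test_monotone_in_distance(self):
        cfg = GaussianConfig(bandwidth_rule="fixed", gamma=1.0, standardize=False)
        rows = [[0.0, 0], [0.5, 0], [2.0, 0]]
        sm = gaussian_similarity(feat_table(rows), cfg)
        assert sm.values[0, 1] > sm.values[0, 2]

    def test_missing_values_mean_imputed(self):
        x = np.array([[1.0, np.nan], [3.0, 2.0], [5.0, 4.0]])
        sm = gaussian_similarity(feat_table(x),
                                 GaussianConfig(bandwidth_rule="fixed", gamma=0.1,
                                                standardize=False))
        imputed = x.copy()
        imputed[0, 1] = 3.0  # column mean of observed
        np.testing.assert_allclose(sm.values, oracles.gaussian_matrix(imputed, 0.1),
                                   atol=1e-9)


class TestAbsPearson:
    def test_affine_invariance(self):
        x = np.array([1.0, 2, 3, 5])
        sm = abs_pearson_similarity(feat_table(np.vstack([x, 2 * x + 3]), "expression"))
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_absolute(self):
        sm = abs_pearson_similarity(feat_table([[1.0, 2, 3], [3.0, 2, 1]], "expression"))
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_derived_example(self):
        sm = abs_pearson_similarity(feat_table([[1.0, 2, 3, 4], [1.0, 3, 2, 4]], "expression"))
        assert sm.values[0, 1] == pytest.approx(0.8, abs=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(7, 9))
        sm = abs_pearson_similarity(feat_table(x, "expression"))
        for i in range(7):
            for j in range(i + 1, 7):
                assert sm.values[i, j] == pytest.approx(
                    abs(oracles.pearson(x[i], x[j])), abs=1e-9)

    def test_zero_variance_row(self):
        sm = abs_pearson_similarity(feat_table([[1.0, 1, 1], [1.0, 2, 3]], "expression"))
        assert sm.values[0, 1] == 0.0 and sm.values[0, 0] == 1.0

    def test_pairwise_complete_missing(self):
        x = np.array([[1.0, 2, 3, np.nan], [1.0, 3, 2, 4.0]])
        sm = abs_pearson_similarity(feat_table(x, "expression"))
        assert sm.values[0, 1] == pytest.approx(
            abs(oracles.pearson([1, 2, 3], [1, 3, 2])), abs=1e-9)


class TestCombineMax:
    def test_self_identity(self):
        sm = random_similarity(np.random.default_rng(1), 5)
        out = combine_max([sm, sm])
        np.testing.assert_allclose(out.values, sm.values, atol=1e-12)

    def test_elementwise_oracle_and_invariants(self):
        rng = np.random.default_rng(2)
        mats = [random_similarity(rng, 6) for _ in range(3)]
        out = combine_max(mats)
        expect = np.maximum.reduce([m.values for m in mats])
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(out.values, expect, atol=1e-12)
        out.validate()
        for m in mats:
            assert (out.values >= m.values - 1e-12).all()

    def test_misaligned_ids_error(self):
        rng = np.random.default_rng(3)
        a = random_similarity(rng, 4)
        b = random_similarity(rng, 5)
        with pytest.raises(KronfuseError):
            combine_max([a, b])

    def test_unavailable_entities(self):
        rng = np.random.default_rng(4)
        a = random_similarity(rng, 4)
        b = random_similarity(rng, 4)
        a.available = np.array([True, True, False, False])
        b.available = np.array([True, False, True, False])
        out = combine_max([a, b])
        # pair (1,2): no shared source -> 0; pair (0,1): only source a
        assert out.values[1, 2] == 0.0
        assert out.values[0, 1] == pytest.approx(a.values[0, 1])
        assert out.values[3, 3] == 1.0
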