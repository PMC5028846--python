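import numpy as np
import pytest

import oracles
from kronfuse import (
    EvalConfig,
    KronfuseError,
    PairKernel,
    ResponseMatrix,
    SvmConfig,
    cross_validate,
    pr_aupr,
    response_profile_similarity,
    roc_auc,
    similarity_correlation,
    tissue_stratified,
)
from kronfuse.containers import SimilarityMatrix
from kronfuse.evaluate import ResponseProfileSimilarityConfig
from kronfuse.labels import LabelMatrix


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert auc == 1.0

    def test_four_point_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1])
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(
            oracles.auc_concordance([0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1]))

    def test_null_behaviour(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=1000)
        labels = np.where(rng.random(1000) < 0.3, 1, -1)
        auc, _ = roc_auc(scores, labels)
        assert 0.45 <= auc <= 0.55

    def test_matches_concordance_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)  # rounded -> ties occur
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(labels)) < 2:
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(oracles.auc_concordance(scores, labels),
                                        abs=1e-9)

    def test_one_class_errors(self):
        with pytest.raises(KronfuseError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAupr:
    def test_perfect_is_one(self):
        ap, _ = pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert ap == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        labels = [1, -1, -1, -1, 1, -1, -1, -1]
        ap, _ = pr_aupr([0.5] * 8, labels)
        assert ap == pytest.approx(0.25)

    def test_four_point_example_matches_oracle(self):
        scores, labels = [0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1]
        ap, _ = pr_aupr(scores, labels)
        assert ap == pytest.approx(oracles.average_precision(scores, labels), abs=1e-9)
        assert ap == pytest.approx(5 / 6)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = np.where(rng.random(n) < 0.4, 1, -1)
            if len(set(labels)) < 2:
                continue
            ap, _ = pr_aupr(scores, labels)
            assert ap == pytest.approx(
                oracles.average_precision(list(scores), list(labels)), abs=1e-9)


def toy_label_matrix(rng, n_cells=12, n_drugs=6, p_pos=0.4):
    labels = np.where(rng.random((n_cells, n_drugs)) < p_pos, 1, -1)
    missing = np.zeros_like(labels, dtype=bool)
    return LabelMatrix([f"c{i}" for i in range(n_cells)],
                       [f"d{j}" for j in range(n_drugs)], labels, missing)


def toy_kernel(rng, n_cells=12, n_drugs=6):
    from conftest import random_similarity

    s_cell = random_similarity(rng, n_cells)
    s_cell.entity_ids = [f"c{i}" for i in range(n_cells)]
    s_drug = random_similarity(rng, n_drugs)
    s_drug.entity_ids = [f"d{j}" for j in range(n_drugs)]
    return PairKernel(s_cell, s_drug)


class TestCrossValidate:
    def test_every_pair_tested_once(self):
        rng = np.random.default_rng(3)
        res = cross_validate(toy_kernel(rng), toy_label_matrix(rng),
                             SvmConfig(C_grid=(1.0,)),
                             EvalConfig(outer_folds=4, seed=0))
        assert len(res.pairs) == 72
        counts = np.bincount(res.fold_of_pair, minlength=4)
        assert counts.sum() == 72 and (counts > 0).all()
        assert not np.isnan(res.scores).any()

    def test_label_shuffle_gives_null_auc(self, small_fused):
        cells, drugs, lm = small_fused
        rng = np.random.default_rng(5)
        labels = lm.labels.copy()
        obs = labels[~lm.missing & (labels != 0)]
        rng.shuffle(obs)
        labels[~lm.missing & (labels != 0)] = obs
        shuffled = LabelMatrix(lm.cell_ids, lm.drug_ids, labels, lm.missing)
        pk = PairKernel(cells["Comb_c"], drugs["Comb_d"])
        res = cross_validate(pk, shuffled, SvmConfig(C_grid=(1.0,)),
                             EvalConfig(outer_folds=5, seed=0))
        assert 0.42 <= res.pooled_auc <= 0.58

    def test_cell_split_never_leaks_cells(self):
        rng = np.random.default_rng(6)
        res = cross_validate(toy_kernel(rng, 16, 5), toy_label_matrix(rng, 16, 5),
                             SvmConfig(C_grid=(1.0,)),
                             EvalConfig(outer_folds=4, split_unit="cell", seed=1))
        for k in range(4):
            test_cells = {c for (c, _), f in zip(res.pairs, res.fold_of_pair) if f == k}
            train_cells = {c for (c, _), f in zip(res.pairs, res.fold_of_pair) if f != k}
            assert not (test_cells & train_cells)


class TestTissueStratified:
    def test_single_tissue_equals_pooled(self):
        rng = np.random.default_rng(7)
        res = cross_validate(toy_kernel(rng), toy_label_matrix(rng),
                             SvmConfig(C_grid=(1.0,)), EvalConfig(outer_folds=3))
        tissue = {c: "LUNG" for c, _ in res.pairs}
        strat = tissue_stratified(res, tissue)
        assert strat["LUNG"]["auc"] == pytest.approx(res.pooled_auc)
        assert strat["LUNG"]["n_pairs"] == len(res.pairs)

    def test_partition_counts_sum(self):
        rng = np.random.default_rng(8)
        res = cross_validate(toy_kernel(rng), toy_label_matrix(rng),
                             SvmConfig(C_grid=(1.0,)), EvalConfig(outer_folds=3))
        cells = sorted({c for c, _ in res.pairs})
        tissue = {c: ("LUNG" if i % 2 else "SKIN") for i, c in enumerate(cells)}
        strat = tissue_stratified(res, tissue)
        assert sum(v["n_pairs"] for v in strat.values()) == len(res.pairs)


class TestResponseProfileSimilarity:
    def test_identical_profiles(self):
        rm = ResponseMatrix(["c1", "c2", "c3"], ["d1", "d2"],
                            [[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]])
        sm = response_profile_similarity(rm, "cells")
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_two_profile_mean_rule(self):
        rm = ResponseMatrix(["c1", "c2"], ["d1", "d2"], [[0.0, 0.0], [1.0, 3.0]])
        sm = response_profile_similarity(rm, "cells")
        assert sm.values[0, 1] == pytest.approx(np.exp(-1))

    def test_disjoint_missingness_gives_zero_entry(self):
        rm = ResponseMatrix(["c1", "c2", "c3"], ["d1", "d2", "d3", "d4"],
                            [[1.0, 2.0, np.nan, np.nan],
                             [np.nan, np.nan, 1.0, 2.0],
                             [1.0, 2.0, 3.0, 4.0]])
        sm = response_profile_similarity(rm, "cells")
        assert sm.values[0, 1] == 0.0

    def test_drug_axis(self):
        rm = ResponseMatrix(["c1", "c2"], ["d1", "d2", "d3"],
                            [[1.0, 1.0, 4.0], [2.0, 2.0, 0.0]])
        sm = response_profile_similarity(
            rm, "drugs", ResponseProfileSimilarityConfig("fixed", 1.0))
        assert sm.entity_ids == ["d1", "d2", "d3"]
        assert sm.values[0, 1] == pytest.approx(1.0)


class TestSimilarityCorrelation:
    def test_self_correlation_is_one(self):
        from conftest import random_similarity

        sm = random_similarity(np.random.default_rng(9), 10)
        out = similarity_correlation(sm, sm)
        assert out["pcc"] == pytest.approx(1.0)

    def test_independent_matrices_low_pcc(self):
        from conftest import random_similarity

        rng = np.random.default_rng(10)
        a = random_similarity(rng, 50)
        b = random_similarity(rng, 50)
        out = similarity_correlation(a, b)
        assert abs(out["pcc"]) < 0.2

    def test_hand_built_matches_oracle(self):
        ids = list("abcd")
        fa = np.array([[1, .2, .4, .6], [.2, 1, .1, .3],
                       [.4, .1, 1, .5], [.6, .3, .5, 1]])
        fr = np.array([[1, .3, .5, .5], [.3, 1, .2, .4],
                       [.5, .2, 1, .6], [.5, .4, .6, 1]])
        out = similarity_correlation(SimilarityMatrix(ids, fa),
                                     SimilarityMatrix(ids, fr))
        iu = np.triu_indices(4, 1)
        assert out["pcc"] == pytest.approx(oracles.pearson(fa[iu], fr[iu]), abs=1e-9)

    def test_bins_ordered_when_coupled(self):
        from conftest import random_similarity

        sm = random_similarity(np.random.default_rng(11), 30)
        out = similarity_correlation(sm, sm)
        assert out["bins"]["low"]["mean"] < out["bins"]["high"]["mean"]
        assert out["ttests"]["high_vs_moderate"]["t"] > 0
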