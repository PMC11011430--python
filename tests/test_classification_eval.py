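import logging

import numpy as np
import pandas as pd
import pytest

from gleason_sig import (
    CLASS_ORDER,
    KNNConfig,
    compare_gene_sets,
    correlate_with_grade,
    knn_predict_proba,
    roc_auc_ovr,
    separation_score,
    top_k,
)
from gleason_sig._knn import encode_labels

from _oracles import knn_proba_bruteforce, mann_whitney_auc
from conftest import annotations_for, expr_from_log2


class TestKnnPredictProba:
    def test_single_class_neighborhood_gives_probability_one(self):
        rng = np.random.default_rng(0)
        train = np.vstack([rng.normal(0, 0.1, size=(12, 2)), rng.normal(10, 0.1, size=(12, 2))])
        labels = ["low"] * 12 + ["high"] * 12
        proba = knn_predict_proba(train, labels, train[:1], KNNConfig(seed=0, transform="raw"))
        assert proba.iloc[0]["low"] == 1.0

    def test_vote_fractions_seven_three(self):
        # ten nearest neighbors: 7 low, 3 high
        train = np.array([[0.0]] * 7 + [[0.5]] * 3 + [[50.0]] * 5)
        labels = ["low"] * 7 + ["high"] * 3 + ["normal"] * 5
        proba = knn_predict_proba(train, labels, np.array([[0.0]]), KNNConfig(transform="raw"))
        assert proba.iloc[0].tolist() == [0.0, 0.7, 0.3]

    def test_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(33)
        train = rng.uniform(0, 100, size=(30, 4))
        test = rng.uniform(0, 100, size=(12, 4))
        labels = list(rng.choice(CLASS_ORDER, size=30))
        proba = knn_predict_proba(train, labels, test, KNNConfig(k_neighbors=5, transform="raw"))
        expected = knn_proba_bruteforce(train, encode_labels(labels), test, k=5)
        np.testing.assert_allclose(proba.to_numpy(), expected, atol=1e-12)

    def test_rows_sum_to_one_and_training_order_irrelevant(self):
        rng = np.random.default_rng(8)
        train = rng.uniform(0, 50, size=(40, 3))
        labels = np.array(list(rng.choice(CLASS_ORDER, size=40)))
        test = rng.uniform(0, 50, size=(15, 3))
        cfg = KNNConfig(k_neighbors=7, transform="raw")
        base = knn_predict_proba(train, labels, test, cfg)
        np.testing.assert_allclose(base.sum(axis=1), 1.0, atol=1e-12)
        perm = rng.permutation(40)
        shuffled = knn_predict_proba(train[perm], labels[perm], test, cfg)
        np.testing.assert_allclose(base.to_numpy(), shuffled.to_numpy(), atol=1e-12)

    def test_fewer_training_samples_than_k_rejected(self):
        with pytest.raises(ValueError, match="k=10"):
            knn_predict_proba(np.ones((5, 2)), ["low"] * 5, np.ones((1, 2)))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = ["normal"] * 5 + ["low"] * 5
        proba = np.zeros((10, 3))
        proba[:5, 0] = 1.0
        proba[5:, 1] = 1.0
        rocs = roc_auc_ovr(labels, proba)
        assert rocs["normal"].auroc == 1.0
        assert rocs["low"].auroc == 1.0

    def test_constant_scores_give_half(self):
        labels = ["normal"] * 6 + ["low"] * 6 + ["high"] * 6
        proba = np.full((18, 3), 1 / 3)
        rocs = roc_auc_ovr(labels, proba)
        for cls in CLASS_ORDER:
            assert rocs[cls].auroc == pytest.approx(0.5, abs=1e-12)

    def test_random_scores_near_half(self):
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = list(rng.permutation(["normal", "low", "high"] * 67)[:200])
            proba = rng.dirichlet(np.ones(3), size=200)
            rocs = roc_auc_ovr(labels, proba)
            aurocs.append(np.mean([rocs[c].auroc for c in CLASS_ORDER]))
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.08)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(40):
            n = int(rng.integers(10, 100))
            labels = list(rng.choice(CLASS_ORDER, size=n))
            if len(set(labels)) < 2:
                continue
            # coarse scores so ties actually occur
            proba = np.round(rng.dirichlet(np.ones(3), size=n), 1)
            rocs = roc_auc_ovr(labels, proba)
            truth = np.asarray(labels)
            for i, cls in enumerate(CLASS_ORDER):
                if rocs[cls] is None:
                    continue
                expected = mann_whitney_auc(proba[:, i], truth == cls)
                assert rocs[cls].auroc == pytest.approx(expected, abs=1e-10)

    def test_absent_class_flagged(self, caplog):
        with caplog.at_level(logging.WARNING):
            rocs = roc_auc_ovr(["low", "high", "low", "high"], np.full((4, 3), 1 / 3))
        assert rocs["normal"] is None

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        labels = list(rng.choice(CLASS_ORDER, size=60))
        proba = rng.dirichlet(np.ones(3), size=60)
        for roc in roc_auc_ovr(labels, proba).values():
            assert (np.diff(roc.fpr) >= 0).all()
            assert (np.diff(roc.tpr) >= 0).all()


def _planted_cohort(seed, n_genes=120, n_planted=8, effect=0.8):
    from gleason_sig import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_per_group=(20, 14, 30, 22, 16, 30),
        n_genes=n_genes,
        n_planted=n_planted,
        effect_size=effect,
        n_blocks=0,
        seed=seed,
    )
    return generate_cohort(cfg)


class TestCompareGeneSets:
    def test_planted_set_beats_decoys(self):
        margins = []
        for seed in range(10):
            expr, ann, truth = _planted_cohort(seed)
            decoys = expr.gene_ids[-8:]
            table = compare_gene_sets(
                {"planted": truth.planted_gene_ids, "decoy": decoys}, expr, ann, KNNConfig(seed=seed)
            )
            table = table.set_index("set")
            auroc_cols = [f"auroc_{c}" for c in CLASS_ORDER]
            margins.append(table.loc["planted", auroc_cols].mean() - table.loc["decoy", auroc_cols].mean())
        assert np.median(margins) > 0

    def test_duplicated_set_gives_identical_rows(self, small_cohort):
        expr, ann, _ = small_cohort
        genes = expr.gene_ids[:4]
        table = compare_gene_sets({"a": genes, "b": genes}, expr, ann, KNNConfig(seed=3))
        a = table[table["set"] == "a"].drop(columns="set").reset_index(drop=True)
        b = table[table["set"] == "b"].drop(columns="set").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_single_gene_set_allowed(self, small_cohort):
        expr, ann, _ = small_cohort
        table = compare_gene_sets({"solo": [expr.gene_ids[0]]}, expr, ann, KNNConfig(seed=1))
        assert len(table) == 1

    def test_missing_genes_dropped_with_warning(self, small_cohort, caplog):
        expr, ann, _ = small_cohort
        with caplog.at_level(logging.WARNING):
            table = compare_gene_sets(
                {"partial": [expr.gene_ids[0], "NOT_A_GENE"]}, expr, ann, KNNConfig(seed=1)
            )
        assert table.loc[0, "n_genes"] == 1
        assert "dropping" in caplog.text

    def test_fully_absent_set_is_an_error(self, small_cohort):
        expr, ann, _ = small_cohort
        with pytest.raises(KeyError, match="ghost"):
            compare_gene_sets({"ghost": ["NOPE1", "NOPE2"]}, expr, ann)


class TestSeparationScore:
    def test_distant_noiseless_centroids(self):
        rng = np.random.default_rng(1)
        blocks, labels, samples = [], [], []
        for i, cls in enumerate(CLASS_ORDER):
            blocks.append(4 + 10 * i + rng.normal(0, 0.01, size=(5, 10)))
            labels += [cls] * 10
        expr = expr_from_log2(np.hstack(blocks))
        ann = annotations_for(expr.sample_ids, labels)
        assert separation_score(expr, ann) > 0.9

    def test_shuffled_labels_score_near_zero(self):
        scores = []
        for seed in range(20):
            expr, ann, _ = _planted_cohort(seed, n_genes=40)
            rng = np.random.default_rng(seed + 100)
            shuffled = ann.copy()
            shuffled["class3"] = rng.permutation(ann["class3"].to_numpy())
            scores.append(separation_score(expr, shuffled))
        assert abs(np.mean(scores)) < 0.1

    def test_top_genes_separate_better_than_all(self):
        deltas = []
        for seed in range(10):
            expr, ann, _ = _planted_cohort(seed, n_genes=400, n_planted=30, effect=0.5)
            records = correlate_with_grade(expr, ann)
            top = top_k(records, 50)
            deltas.append(separation_score(expr, ann, top) - separation_score(expr, ann))
        assert np.median(deltas) > 0

    def test_tiny_subset_rejected(self, small_cohort):
        expr, ann, _ = small_cohort
        with pytest.raises(ValueError):
            separation_score(expr, ann, [expr.gene_ids[0]])
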