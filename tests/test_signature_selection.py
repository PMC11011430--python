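import logging
from math import comb

import numpy as np
import pandas as pd
import pytest

from gleason_sig import (
    KNNConfig,
    SelectionConfig,
    build_decorrelation_network,
    correlate_with_grade,
    count_combinations,
    enumerate_combinations,
    evaluate_combination,
    gene_marginal_scores,
    generate_cohort,
    run_selection_pipeline,
    SyntheticConfig,
)

from _oracles import pearson_r
from conftest import annotations_for, expr_from_log2


class TestEnumerateCombinations:
    def test_counts_match_binomial_formula(self):
        genes = [f"G{i}" for i in range(20)]
        combos = list(enumerate_combinations(genes, {3, 4, 5, 6}))
        assert len(combos) == sum(comb(20, s) for s in (3, 4, 5, 6)) == 60249
        assert count_combinations(20, {3, 4, 5, 6}) == 60249

    def test_each_subset_once_in_lexicographic_order(self):
        combos = list(enumerate_combinations(["c", "a", "b"], {2}))
        assert combos == [("a", "b"), ("a", "c"), ("b", "c")]
        assert len(set(combos)) == len(combos)

    def test_full_size_single_tuple(self):
        assert list(enumerate_combinations(["a", "b", "c"], {3})) == [("a", "b", "c")]

    def test_pairs_of_five(self):
        assert len(list(enumerate_combinations(list("abcde"), {2}))) == 10

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_combinations(["a", "b"], {3}))


class TestDecorrelationNetwork:
    def _expr(self, values):
        return expr_from_log2(values)

    def test_uncorrelated_noise_genes_fully_linked(self):
        rng = np.random.default_rng(14)
        values = rng.normal(5, 1, size=(3, 200))
        expr = self._expr(values)
        # fixture sanity: empirical |r| below threshold for all pairs
        log2x = np.log2(expr.values + 1)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(pearson_r(log2x[i], log2x[j])) < 0.2
        graph, selected = build_decorrelation_network(expr, expr.gene_ids, degree_min=1)
        assert sorted(selected) == expr.gene_ids
        assert all(graph.degree[g] == 2 for g in expr.gene_ids)

    def test_correlated_block_has_no_internal_edges(self):
        rng = np.random.default_rng(15)
        shared = rng.normal(0, 1, size=100)
        values = 5 + np.vstack([shared, shared, shared]) + rng.normal(0, 1e-6, size=(3, 100))
        graph, _ = build_decorrelation_network(self._expr(values), ["G000", "G001", "G002"], degree_min=0)
        assert graph.number_of_edges() == 0

    def test_edges_match_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(16)
        n_genes = 30
        values = rng.normal(5, 1, size=(n_genes, 80))
        values[5] = values[4] + rng.normal(0, 0.1, size=80)  # one strongly linked pair
        expr = self._expr(values)
        graph, _ = build_decorrelation_network(expr, expr.gene_ids, r_threshold=0.2, degree_min=0)
        log2x = np.log2(expr.values + 1)
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                expected = abs(pearson_r(log2x[i], log2x[j])) < 0.2
                assert graph.has_edge(expr.gene_ids[i], expr.gene_ids[j]) == expected

    def test_constant_gene_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(17)
        values = rng.normal(5, 1, size=(3, 50))
        values[1] = 3.0
        with caplog.at_level(logging.WARNING):
            graph, _ = build_decorrelation_network(self._expr(values), ["G000", "G001", "G002"], degree_min=0)
        assert "G001" not in graph
        assert "constant" in caplog.text

    def test_selection_sorted_by_degree_and_capped(self):
        rng = np.random.default_rng(18)
        values = rng.normal(5, 1, size=(10, 150)        )
        expr = self._expr(values)
        graph, selected = build_decorrelation_network(expr, expr.gene_ids, degree_min=0, max_selected=4)
        assert len(selected) == 4
        degrees = [graph.degree[g] for g in selected]
        assert degrees == sorted(degrees, reverse=True)

    def test_too_few_candidates_rejected(self, small_cohort):
        expr, _, _ = small_cohort
        with pytest.raises(ValueError):
            build_decorrelation_network(expr, [expr.gene_ids[0]])


def _separable_cohort(n_per_class=20, n_genes=4, sep=8.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    centers = {"normal": 0.0, "low": sep, "high": 2 * sep}
    blocks, labels = [], []
    for cls in ("normal", "low", "high"):
        blocks.append(5 + centers[cls] + rng.normal(0, noise, size=(n_genes, n_per_class)))
        labels += [cls] * n_per_class
    expr = expr_from_log2(np.hstack(blocks))
    return expr, labels


class TestEvaluateCombination:
    def test_separable_classes_give_perfect_accuracy(self):
        expr, labels = _separable_cohort()
        result = evaluate_combination(expr.gene_ids, expr, labels, KNNConfig(seed=1))
        assert result.accuracy == 1.0

    def test_deterministic_given_seed(self, small_cohort):
        expr, ann, _ = small_cohort
        labels = ann["class3"].tolist()
        genes = expr.gene_ids[:4]
        cfg = KNNConfig(seed=5)
        a = evaluate_combination(genes, expr, labels, cfg, with_auroc=True)
        b = evaluate_combination(genes, expr, labels, cfg, with_auroc=True)
        assert a == b

    def test_accuracy_invariant_to_gene_order(self, small_cohort):
        expr, ann, _ = small_cohort
        labels = ann["class3"].tolist()
        genes = expr.gene_ids[:5]
        cfg = KNNConfig(seed=2)
        fwd = evaluate_combination(genes, expr, labels, cfg)
        rev = evaluate_combination(genes[::-1], expr, labels, cfg)
        assert fwd.accuracy == rev.accuracy

    def test_repeated_splits_average(self, small_cohort):
        expr, ann, _ = small_cohort
        labels = ann["class3"].tolist()
        genes = expr.gene_ids[:3]
        singles = [
            evaluate_combination(genes, expr, labels, KNNConfig(seed=s)).accuracy for s in (3, 4, 5)
        ]
        mean = evaluate_combination(genes, expr, labels, KNNConfig(seed=3, n_repeats=3)).accuracy
        assert mean == pytest.approx(np.mean(singles), abs=1e-12)

    def test_unstratified_split_can_fail_loudly(self):
        # a single normal sample: an unstratified 50:50 split orphans the
        # class from the training half about half the time
        expr, labels = _separable_cohort(n_per_class=12)
        labels = ["normal"] + ["low"] * 17 + ["high"] * 18
        errors = 0
        for seed in range(20):
            try:
                evaluate_combination(
                    expr.gene_ids[:2], expr, labels,
                    KNNConfig(seed=seed, stratified=False, k_neighbors=3),
                )
            except ValueError:
                errors += 1
        assert errors > 0


class TestMarginalScores:
    def test_uniform_accuracy_gives_uniform_scores(self):
        results = pd.DataFrame({"genes": [("a", "b"), ("b", "c"), ("a", "c")], "accuracy": [0.5] * 3})
        scores = gene_marginal_scores(results)
        assert set(scores) == {0.5}

    def test_discriminating_gene_ranks_first(self):
        results = pd.DataFrame(
            {"genes": [("hero", "x"), ("hero", "y"), ("x", "y")], "accuracy": [1.0, 1.0, 0.0]}
        )
        assert gene_marginal_scores(results).index[0] == "hero"

    def test_ties_broken_by_gene_id(self):
        results = pd.DataFrame({"genes": [("b",), ("a",)], "accuracy": [0.7, 0.7]})
        assert gene_marginal_scores(results).index.tolist() == ["a", "b"]


@pytest.fixture(scope="module")
def informative_cohort():
    # exactly 8 informative genes, everything else pure noise
    cfg = SyntheticConfig(
        n_per_group=(24, 18, 40, 30, 20, 40),
        n_genes=60,
        n_planted=8,
        effect_size=1.0,
        n_blocks=0,
        noise_sd=0.5,
        seed=23,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def pipeline_config():
    return SelectionConfig(
        top_k_primary=10,
        top_k_network=30,
        max_network_candidates=10,
        route_sizes=(3, 4),
        final_sizes=(3, 4, 5, 6, 7, 8),
        knn=KNNConfig(seed=31),
    )


@pytest.fixture(scope="module")
def report(informative_cohort, pipeline_config):
    expr, ann, _ = informative_cohort
    records = correlate_with_grade(expr, ann)
    return run_selection_pipeline(expr, ann, records, pipeline_config)


class TestSelectionPipeline:
    def test_signature_contains_only_planted_genes(self, informative_cohort, report):
        # with strong effects the classifier saturates, so the smaller-size
        # tie-break yields a subset of the planted genes rather than all 8;
        # the essential recovery property is that no noise gene enters
        _, _, truth = informative_cohort
        assert set(report.final_signature) <= set(truth.planted_gene_ids)
        assert report.final_accuracy == 1.0

    def test_report_is_deterministic(self, informative_cohort, pipeline_config, report):
        expr, ann, _ = informative_cohort
        records = correlate_with_grade(expr, ann)
        again = run_selection_pipeline(expr, ann, records, pipeline_config)
        assert again.final_signature == report.final_signature
        assert again.final_accuracy == report.final_accuracy
        assert again.final_auroc == report.final_auroc
        pd.testing.assert_frame_equal(again.results_final, report.results_final)

    def test_pool_structure(self, report, pipeline_config):
        assert len(report.pool_a) == pipeline_config.pool_size
        assert len(report.pool_b) == pipeline_config.pool_size
        overlap = set(report.pool_a) & set(report.pool_b)
        assert len(report.pooled) == 16 - len(overlap)
        assert set(report.final_signature) <= set(report.pooled)

    def test_signature_beats_random_subsets(self, informative_cohort, report):
        expr, ann, _ = informative_cohort
        labels = ann["class3"].tolist()
        rng = np.random.default_rng(0)
        noise_genes = [g for g in expr.gene_ids if g not in report.final_signature]
        decoy = list(rng.choice(noise_genes, size=len(report.final_signature), replace=False))
        decoy_acc = evaluate_combination(decoy, expr, labels, KNNConfig(seed=31)).accuracy
        assert report.final_accuracy > decoy_acc

    def test_small_pool_rejected(self, informative_cohort):
        expr, ann, _ = informative_cohort
        records = correlate_with_grade(expr, ann)
        cfg = SelectionConfig(
            top_k_primary=4, top_k_network=10, max_network_candidates=4, degree_min=2,
            pool_size=2, route_sizes=(2,), final_sizes=(9,), knn=KNNConfig(seed=1),
        )
        with pytest.raises(ValueError, match="smaller than the smallest"):
            run_selection_pipeline(expr, ann, records, cfg)
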