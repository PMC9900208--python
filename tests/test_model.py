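"""Classifier training, ranking and cross-validation, including the
brute-force auPRC oracle and the permutation-null calibration check."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score
from scipy.stats import spearmanr

from netprio.features import FeatureMatrix
from netprio.fixtures import expected_recovery, make_separable_features
from netprio.labels import LabelAssignment
from netprio.model import (
    ModelError,
    cross_validate,
    rank_predictions,
    train,
)


def auprc_all_thresholds_oracle(y_true, scores):
    """Step-method auPRC by explicit enumeration of every distinct threshold."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    n_pos = y_true.sum()
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = float(y_true[called].sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def shuffled_labels(labeled: np.ndarray, n_pos: int, seed: int) -> LabelAssignment:
    perm = np.random.default_rng(seed).permutation(labeled)
    return LabelAssignment(
        positives=set(map(int, perm[:n_pos])),
        negatives=set(map(int, perm[n_pos:])),
    )


class TestTrain:
    def test_separable_clusters_rank_all_positives_first(self):
        fm, labels = make_separable_features(n_pos=10, n_neg=20, seed=3)
        result = train(fm, labels, seed=0)
        pos = sorted(labels.positives)
        neg = sorted(labels.negatives)
        assert result.probabilities[pos].min() > result.probabilities[neg].max()

    def test_probabilities_cover_all_genes_including_unlabeled(self):
        fm, labels = make_separable_features(n_pos=10, n_neg=20, seed=3)
        extra = np.vstack([fm.values, np.zeros((5, fm.dim))])
        fm_ext = FeatureMatrix(kind=fm.kind, values=extra, params=fm.params)
        result = train(fm_ext, labels, seed=0)
        assert len(result.probabilities) == 35
        assert np.all((result.probabilities >= 0) & (result.probabilities <= 1))

    def test_deterministic_bitwise_given_seed(self, bench_adjacency, bench_labels):
        a = train(bench_adjacency, bench_labels, seed=4)
        b = train(bench_adjacency, bench_labels, seed=4)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.weights, b.weights)

    def test_planted_module_recovery_from_partial_input(self, benchmark,
                                                        bench_adjacency, bench_labels):
        result = train(bench_adjacency, bench_labels, seed=0)
        top30 = np.flatnonzero(result.ranks <= 30)
        assert len(benchmark.held_out & set(map(int, top30))) >= 8

    def test_too_few_positives_rejected(self):
        fm, _ = make_separable_features(n_pos=10, n_neg=20, seed=0)
        bad = LabelAssignment(positives={0, 1}, negatives=set(range(10, 30)))
        with pytest.raises(ModelError, match="positives"):
            train(fm, bad, seed=0)

    def test_scale_equivariance_of_ranking(self, bench_adjacency, bench_labels):
        base = train(bench_adjacency, bench_labels, seed=0)
        scaled_fm = FeatureMatrix(
            kind=bench_adjacency.kind,
            values=bench_adjacency.values * 7.5,
            params=bench_adjacency.params,
        )
        scaled = train(scaled_fm, bench_labels, seed=0)
        rho = spearmanr(base.probabilities, scaled.probabilities).statistic
        assert rho >= 0.99


class TestRankPredictions:
    def test_distinct_probabilities_sort_descending(self, tiny_index):
        probs = np.array([0.1, 0.9, 0.5, 0.3, 0.8, 0.2])
        from netprio.model import ModelResult, _ranks_desc

        result = ModelResult(
            weights=np.zeros(2), intercept=0.0, probabilities=probs,
            ranks=_ranks_desc(probs),
            novel_flag=np.array([True, False, True, True, True, True]),
        )
        table = rank_predictions(result, tiny_index)
        assert list(table["rank"]) == [1, 2, 3, 4, 5, 6]
        assert list(table["probability"]) == sorted(probs, reverse=True)
        assert table.iloc[0]["known_or_novel"] == "known"

    def test_equal_probabilities_tie_to_lower_internal_id(self, tiny_index):
        probs = np.array([0.5, 0.9, 0.5, 0.1, 0.2, 0.3])
        from netprio.model import ModelResult, _ranks_desc

        result = ModelResult(
            weights=np.zeros(2), intercept=0.0, probabilities=probs,
            ranks=_ranks_desc(probs), novel_flag=np.ones(6, dtype=bool),
        )
        table = rank_predictions(result, tiny_index)
        tied = table[table["probability"] == 0.5]
        assert list(tied["external_id"]) == ["101", "999"]  # internal 0 before 2


class TestCrossValidate:
    def test_separable_fixture_hits_ceiling_exactly(self):
        fm, labels = make_separable_features(n_pos=20, n_neg=40, seed=1)
        cv = cross_validate(fm, labels, k=5, seed=0)
        assert cv.mean_auroc == 1.0
        for log2_ratio, prior in zip(cv.fold_log2_auprc_over_prior, cv.fold_prior):
            assert log2_ratio == -np.log2(prior)

    def test_k_reduced_when_it_exceeds_positive_count(self):
        fm, labels = make_separable_features(n_pos=6, n_neg=30, seed=2)
        with pytest.warns(UserWarning, match="reducing k"):
            cv = cross_validate(fm, labels, k=10, seed=0)
        assert cv.k == 6

    def test_random_features_balanced_labels_auprc_near_prior(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(kind="embedding", values=rng.normal(size=(80, 10)),
                           params={})
        auprcs = []
        for s in range(20):
            labels = shuffled_labels(np.arange(80), 40, seed=900 + s)
            cv = cross_validate(fm, labels, k=5, seed=s)
            auprcs.append(cv.mean_auprc)
        # prior is 0.5; chance-level auPRC sits slightly above it at small n
        assert abs(float(np.mean(auprcs)) - 0.5) < 0.1

    def test_null_calibration_mean_auroc_near_half(self, bench_adjacency, bench_gsc):
        annotated = np.array(sorted(bench_gsc.all_annotated()))
        means = []
        for s in range(20):
            labels = shuffled_labels(annotated, 50, seed=1000 + s)
            cv = cross_validate(bench_adjacency, labels, k=5, seed=s)
            means.append(cv.mean_auroc)
        assert abs(float(np.mean(means)) - 0.5) <= 0.05

    def test_cv_result_dict_is_json_shaped(self):
        fm, labels = make_separable_features(seed=4)
        d = cross_validate(fm, labels, k=3, seed=0).to_dict()
        assert d["k"] == 3 and len(d["folds"]) == 3
        assert set(d["mean"]) == {"auprc", "log2_auprc_over_prior", "auroc",
                                  "precision_at_npos"}


class TestAuprcOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_average_precision_matches_all_thresholds_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        y = (rng.random(n) < 0.3).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        assert average_precision_score(y, scores) == pytest.approx(
            auprc_all_thresholds_oracle(y, scores), abs=1e-12
        )


def test_expected_recovery_is_one_on_disconnected_modules(tmp_path):
    from netprio.fixtures import make_benchmark
    from netprio.features import build_adjacency
    from netprio.ingestion import load_id_map, load_network, load_gsc, read_gene_list, convert_genes
    from netprio.labels import select_labels

    bench = make_benchmark(tmp_path, n=150, m=3, s=15, p_in=0.6, p_out=0.0,
                           noise_terms=0, seed=3)
    index = load_id_map(bench.paths["id_map"])
    net = load_network(bench.paths["network"], index)
    gsc = load_gsc(bench.paths["gsc"], index)
    universe = set(map(int, np.unique(np.concatenate([net.u, net.v]))))
    report = convert_genes(read_gene_list(bench.paths["genes"]), index)
    labels = select_labels(report.converted, gsc, universe)
    result = train(build_adjacency(net), labels, seed=0)
    assert expected_recovery(bench, result) == 1.0
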