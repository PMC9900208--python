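"""Model-similarity interpretation panels and top-gene subnetwork extraction."""

import numpy as np
import pytest

from netprio.interpret import (
    extract_subnetwork,
    model_similarity,
    subnetwork_to_graphml,
    train_panel,
)
from netprio.model import ModelResult, _ranks_desc, train
from netprio.labels import select_labels

from conftest import make_network, random_network


def fake_result(probs, n_known=0):
    probs = np.asarray(probs, dtype=float)
    novel = np.ones(len(probs), dtype=bool)
    novel[:n_known] = False
    return ModelResult(
        weights=np.zeros(3), intercept=0.0, probabilities=probs,
        ranks=_ranks_desc(probs), novel_flag=novel,
    )


class TestModelSimilarity:
    def test_identical_vector_scores_one_at_rank_one(self):
        user = np.array([1.0, -2.0, 0.5])
        panel = {"SAME": user.copy(), "OTHER": np.array([0.3, 4.0, 1.0]),
                 "THIRD": np.array([-1.0, 0.2, 2.0])}
        table = model_similarity(user, panel).table
        assert table.iloc[0]["term_id"] == "SAME"
        assert table.iloc[0]["rank"] == 1
        assert table.iloc[0]["similarity"] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors_score_zero(self):
        user = np.array([1.0, 0.0])
        table = model_similarity(user, {"ORTH": np.array([0.0, 3.0]),
                                        "OTHER": np.array([1.0, 1.0])}).table
        orth = table[table["term_id"] == "ORTH"]
        assert float(orth["similarity"].iloc[0]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_vector_warns_and_scores_zero(self):
        user = np.array([1.0, 1.0])
        with pytest.warns(UserWarning, match="zero-norm"):
            table = model_similarity(user, {"Z": np.zeros(2),
                                            "A": np.ones(2)}).table
        assert float(table[table["term_id"] == "Z"]["similarity"].iloc[0]) == 0.0

    def test_similarity_is_symmetric_between_panel_members(self):
        rng = np.random.default_rng(0)
        vecs = {f"T{i}": rng.normal(size=6) for i in range(4)}
        for a in vecs:
            for b in vecs:
                sa = model_similarity(vecs[a], {b: vecs[b]}).table["similarity"].iloc[0]
                sb = model_similarity(vecs[b], {a: vecs[a]}).table["similarity"].iloc[0]
                assert sa == pytest.approx(sb, abs=1e-12)

    def test_z_scores_standardized_over_panel(self):
        rng = np.random.default_rng(1)
        panel = {f"T{i}": rng.normal(size=5) for i in range(10)}
        table = model_similarity(rng.normal(size=5), panel).table
        assert float(table["z_score"].mean()) == pytest.approx(0.0, abs=1e-9)
        assert float(table["z_score"].std(ddof=0)) == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            model_similarity(np.ones(3), {"BAD": np.ones(4)})

    def test_pearson_mode_centers_vectors(self):
        user = np.array([1.0, 2.0, 3.0])
        shifted = user + 100.0  # perfectly correlated, poorly aligned
        table = model_similarity(user, {"S": shifted}, metric="pearson").table
        assert table["similarity"].iloc[0] == pytest.approx(1.0, abs=1e-9)


class TestTrainPanel:
    def test_one_weight_vector_per_retained_term(self, bench_adjacency, bench_gsc,
                                                 bench_universe):
        panel = train_panel(bench_adjacency, bench_gsc, bench_universe, seed=0)
        assert len(panel) > 0
        for w in panel.values():
            assert w.shape == (bench_adjacency.dim,)

    def test_term_identical_to_input_ranks_first(self, benchmark, bench_adjacency,
                                                 bench_gsc, bench_universe,
                                                 bench_labels):
        user = train(bench_adjacency, bench_labels, seed=0)
        panel = train_panel(bench_adjacency, bench_gsc, bench_universe, seed=0)
        # make one panel entry the user model itself: same positives, pipeline, seed
        input_term = "USER_INPUT"
        panel[input_term] = user.weights
        table = model_similarity(user.weights, panel).table
        assert table.iloc[0]["term_id"] == input_term
        assert table.iloc[0]["similarity"] == pytest.approx(1.0, abs=1e-12)

    def test_shared_module_models_more_similar_than_disjoint(self, bench_adjacency,
                                                             bench_gsc,
                                                             bench_universe):
        module0 = set(bench_gsc.members("MODULE_0"))
        half_a = set(sorted(module0)[:15])  # two inputs sharing 10/15 genes
        half_b = set(sorted(module0)[5:])
        disjoint = set(bench_gsc.members("MODULE_3"))

        def fit(pos):
            labels = select_labels(pos, bench_gsc, bench_universe)
            return train(bench_adjacency, labels, seed=0).weights

        wa, wb, wd = fit(half_a), fit(half_b), fit(disjoint)
        sim_shared = model_similarity(wa, {"b": wb}).table["similarity"].iloc[0]
        sim_disjoint = model_similarity(wa, {"d": wd}).table["similarity"].iloc[0]
        assert sim_shared > sim_disjoint

    def test_cache_hit_skips_retraining(self, tmp_path, bench_adjacency, bench_gsc,
                                        bench_universe, monkeypatch):
        first = train_panel(bench_adjacency, bench_gsc, bench_universe, seed=0,
                            cache_dir=tmp_path)
        import netprio.interpret as interp

        def boom(*a, **k):  # any retraining attempt is a cache miss
            raise AssertionError("cache miss: train() was called")

        monkeypatch.setattr(interp, "train", boom)
        second = train_panel(bench_adjacency, bench_gsc, bench_universe, seed=0,
                             cache_dir=tmp_path)
        assert set(first) == set(second)
        for tid in first:
            assert np.array_equal(first[tid], second[tid])

    def test_undersized_terms_skipped_not_fatal(self, bench_adjacency, bench_universe):
        from netprio.ingestion import GeneSetCollection

        gsc = GeneSetCollection()
        gsc.terms = {
            "TINY": ("tiny", frozenset({0, 1})),
            "OK": ("ok", frozenset(range(40, 70))),
            "ALSO": ("also", frozenset(range(100, 140))),
        }
        panel = train_panel(bench_adjacency, gsc, bench_universe, seed=0)
        assert "TINY" not in panel


class TestExtractSubnetwork:
    def test_k_one_yields_single_node_no_edges(self, tiny_index):
        net = make_network(6, [(0, 1, 1.0), (1, 2, 1.0)])
        sub = extract_subnetwork(net, fake_result([0.9, 0.5, 0.4, 0.1, 0.2, 0.3]),
                                 tiny_index, k=1)
        assert sub.n_nodes == 1 and sub.n_edges == 0
        assert sub.nodes.iloc[0]["external_id"] == "101"

    def test_top_k_inside_clique_has_closed_form_edge_count(self, tiny_index):
        k = 4
        edges = [(i, j, 1.0) for i in range(k) for j in range(i + 1, k)]
        net = make_network(6, edges + [(4, 5, 1.0)])
        probs = [0.9, 0.8, 0.7, 0.6, 0.1, 0.05]
        sub = extract_subnetwork(net, fake_result(probs), tiny_index, k=k)
        assert sub.n_edges == k * (k - 1) // 2

    def test_path_graph_induced_edges_listed_by_hand(self, tiny_index):
        # path 0-1-2-3-4; top 3 = {0, 1, 4} -> only edge (0, 1) survives
        net = make_network(6, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0)])
        sub = extract_subnetwork(net, fake_result([0.9, 0.8, 0.1, 0.05, 0.7, 0.0]),
                                 tiny_index, k=3)
        assert {tuple(r) for r in sub.edges[["u", "v"]].itertuples(index=False)} == {(0, 1)}

    def test_subnetwork_edges_subset_of_network_edges(self, tiny_index):
        rng = np.random.default_rng(3)
        for trial in range(5):
            net = random_network(6, 0.5, rng)
            probs = rng.random(6)
            k = int(rng.integers(1, 7))
            sub = extract_subnetwork(net, fake_result(probs), tiny_index, k=k)
            net_edges = {(a, b) for a, b, _ in net.edge_set()}
            for row in sub.edges.itertuples(index=False):
                assert (row.u, row.v) in net_edges or (row.v, row.u) in net_edges

    def test_annotations_carried_from_model_result(self, tiny_index):
        net = make_network(6, [(0, 1, 2.5)])
        sub = extract_subnetwork(net, fake_result([0.9, 0.8, 0.1, 0.0, 0.0, 0.0],
                                                  n_known=1), tiny_index, k=2)
        assert list(sub.nodes["known_or_novel"]) == ["known", "novel"]
        assert float(sub.edges["weight"].iloc[0]) == 2.5

    def test_graphml_export_round_trips_node_count(self, tiny_index, tmp_path):
        import networkx as nx

        net = make_network(6, [(0, 1, 1.0), (1, 2, 1.0)])
        sub = extract_subnetwork(net, fake_result([0.9, 0.8, 0.7, 0.1, 0.1, 0.1]),
                                 tiny_index, k=3)
        out = tmp_path / "sub.graphml"
        subnetwork_to_graphml(sub, out)
        g = nx.read_graphml(out)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
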