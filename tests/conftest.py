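"""Shared fixtures: a tiny hand-written gene index, direct Network builders,
and one session-scoped planted benchmark with its derived artifacts."""

import numpy as np
import pytest

from netprio.features import build_adjacency, build_influence
from netprio.fixtures import make_benchmark
from netprio.ingestion import (
    GeneIndex,
    Network,
    convert_genes,
    load_gsc,
    load_id_map,
    load_network,
    read_gene_list,
)
from netprio.labels import select_labels

# ---------------------------------------------------------------------------
# small hand-written inputs
# ---------------------------------------------------------------------------

TINY_ID_MAP = """\
entrez\tsymbol\tensembl_gene\tensembl_protein
101\tAAA\tENSG00000000001\tENSP00000000001
102\tXGENE\tENSG00000000002\tENSP00000000002
999\t101\tENSG00000000003\t
104\tBBB\tENSG00000000004\tENSP00000000004
105\tCCC\tENSG00000000005\tENSP00000000005
106\tDDD\tENSG00000000006\tENSP00000000006
"""


@pytest.fixture()
def tiny_index(tmp_path) -> GeneIndex:
    p = tmp_path / "id_map.tsv"
    p.write_text(TINY_ID_MAP)
    return load_id_map(p)


def make_network(n_nodes: int, edges: list[tuple[int, int, float]]) -> Network:
    """Build a Network directly from a cleaned (u < v) edge list."""
    if edges:
        u, v, w = (np.asarray(x) for x in zip(*edges))
    else:
        u = v = np.empty(0, dtype=np.int64)
        w = np.empty(0, dtype=np.float64)
    return Network(
        n_nodes=n_nodes,
        u=u.astype(np.int64),
        v=v.astype(np.int64),
        w=w.astype(np.float64),
        weighted=True,
    )


def random_network(n: int, p: float, rng: np.random.Generator) -> Network:
    """Erdos-Renyi network with uniform random weights; isolated nodes allowed."""
    iu, iv = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    edges = [
        (int(a), int(b), float(w))
        for a, b, w in zip(iu[keep], iv[keep], 0.5 + rng.random(int(keep.sum())))
    ]
    return make_network(n, edges)


# ---------------------------------------------------------------------------
# session-scoped planted benchmark at the standard study conditions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bench")
    return make_benchmark(outdir, n=500, m=5, s=20, p_in=0.3, p_out=0.01, f=0.5,
                          noise_terms=10, seed=7)


@pytest.fixture(scope="session")
def bench_index(benchmark):
    return load_id_map(benchmark.paths["id_map"])


@pytest.fixture(scope="session")
def bench_net(benchmark, bench_index):
    return load_network(benchmark.paths["network"], bench_index)


@pytest.fixture(scope="session")
def bench_gsc(benchmark, bench_index):
    return load_gsc(benchmark.paths["gsc"], bench_index)


@pytest.fixture(scope="session")
def bench_universe(bench_net):
    return set(map(int, np.unique(np.concatenate([bench_net.u, bench_net.v]))))


@pytest.fixture(scope="session")
def bench_labels(benchmark, bench_index, bench_gsc, bench_universe):
    report = convert_genes(read_gene_list(benchmark.paths["genes"]), bench_index)
    return select_labels(report.converted, bench_gsc, bench_universe)


@pytest.fixture(scope="session")
def bench_adjacency(bench_net):
    return build_adjacency(bench_net)


@pytest.fixture(scope="session")
def bench_influence(bench_net):
    return build_influence(bench_net)
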