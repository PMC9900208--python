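"""Network feature representations: adjacency, RWR influence, node2vec embedding.

Every representation produces a :class:`FeatureMatrix` whose row order is the
internal gene index, so row g is the feature vector of gene g regardless of
representation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

from netprio.ingestion import Network

logger = logging.getLogger(__name__)

# below this node count the influence system is solved densely; above it,
# via a sparse LU factorization applied column-block-wise
DENSE_SOLVE_MAX_NODES = 5000


@dataclass
class FeatureMatrix:
    """Genes-by-features numeric matrix plus the parameters that built it.

    kind is one of "adjacency", "influence", "embedding". For adjacency and
    influence the matrix is square (n x n); for embeddings it is n x dim.
    The influence matrix follows the columns-as-source convention: column v is
    the stationary visiting distribution of a restarting walk from gene v, so
    every column sums to 1.
    """

    kind: str
    values: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        """Check the representation-specific structural invariants."""
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.kind == "adjacency":
            if not np.allclose(self.values, self.values.T):
                raise ValueError("adjacency features must be symmetric")
            if np.any(np.diagonal(self.values) != 0):
                raise ValueError("adjacency diagonal must be zero")
        elif self.kind == "influence":
            colsums = self.values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-8):
                raise ValueError("influence columns must sum to 1")
            if np.any(self.values < -1e-12):
                raise ValueError("influence entries must be non-negative")
        elif self.kind != "embedding":
            raise ValueError(f"unknown feature kind {self.kind!r}")


def dense_adjacency(net: Network) -> np.ndarray:
    A = np.zeros((net.n_nodes, net.n_nodes), dtype=np.float64)
    A[net.u, net.v] = net.w
    A[net.v, net.u] = net.w
    return A


def build_adjacency(net: Network) -> FeatureMatrix:
    """Weighted symmetric adjacency matrix; entry (u, v) is the edge weight."""
    fm = FeatureMatrix(
        kind="adjacency", values=dense_adjacency(net), params={"kind": "adjacency"}
    )
    fm.validate()
    return fm


def _column_normalized_walk_matrix(net: Network) -> sp.csc_matrix:
    """W with W[u, v] = P(step to u | at v); isolated nodes get a self column."""
    n = net.n_nodes
    A = sp.coo_matrix(
        (
            np.concatenate([net.w, net.w]),
            (np.concatenate([net.u, net.v]), np.concatenate([net.v, net.u])),
        ),
        shape=(n, n),
    ).tocsc()
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = colsum == 0
    scale = np.where(isolated, 1.0, colsum)
    W = A @ sp.diags(1.0 / scale)
    if isolated.any():
        idx = np.flatnonzero(isolated)
        W = (W + sp.coo_matrix((np.ones(len(idx)), (idx, idx)), shape=(n, n))).tocsc()
        logger.info("influence: %d isolated nodes received identity columns", len(idx))
    return sp.csc_matrix(W)


def build_influence(net: Network, restart_prob: float = 0.85) -> FeatureMatrix:
    """Random-walk-with-restart influence matrix.

    Solves influence = r (I - (1 - r) W)^{-1} with W the column-normalized
    adjacency and r = restart_prob; column v is the expected long-run visiting
    distribution of a walk that restarts at v with probability r at each step.
    Captures multi-hop connectivity, unlike the raw adjacency.
    """
    if not 0.0 < restart_prob < 1.0:
        raise ValueError(f"restart_prob must be in (0, 1), got {restart_prob}")
    n = net.n_nodes
    W = _column_normalized_walk_matrix(net)
    system = sp.identity(n, format="csc") - (1.0 - restart_prob) * W
    if n <= DENSE_SOLVE_MAX_NODES:
        F = restart_prob * np.linalg.solve(system.toarray(), np.eye(n))
    else:
        lu = spla.splu(system)
        F = np.empty((n, n), dtype=np.float64)
        block = 512
        eye = np.eye(n)
        for start in range(0, n, block):
            F[:, start : start + block] = restart_prob * lu.solve(
                eye[:, start : start + block]
            )
    assert np.all(np.isfinite(F)), "influence solve produced non-finite values"
    F = np.clip(F, 0.0, None)  # clip -1e-17-scale solver noise
    fm = FeatureMatrix(
        kind="influence", values=F, params={"kind": "influence", "restart_prob": restart_prob}
    )
    fm.validate()
    return fm


# ---------------------------------------------------------------------------
# node2vec embedding (biased second-order walks + skip-gram negative sampling)
# ---------------------------------------------------------------------------


def _walk_tables(net: Network):
    nbrs = net.neighbors()
    weights = []
    wmap = {}
    for a, b, c in zip(net.u, net.v, net.w):
        wmap[(int(a), int(b))] = float(c)
        wmap[(int(b), int(a))] = float(c)
    for node, nb in enumerate(nbrs):
        weights.append(np.array([wmap[(node, int(x))] for x in nb], dtype=np.float64))
    return nbrs, weights


def _generate_walks(
    net: Network,
    walk_length: int,
    walks_per_node: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    nbrs, weights = _walk_tables(net)
    nbr_sets = [set(map(int, nb)) for nb in nbrs]
    cumw = [np.cumsum(w) for w in weights]
    first_order = p == 1.0 and q == 1.0
    walks: list[np.ndarray] = []
    n_isolated = 0
    for _ in range(walks_per_node):
        for start in range(net.n_nodes):
            if len(nbrs[start]) == 0:
                n_isolated += 1
                continue  # zero-length walk fallback: vector stays at init
            walk = [start]
            prev = -1
            cur = start
            for _step in range(walk_length - 1):
                nb = nbrs[cur]
                if first_order:
                    cw = cumw[cur]
                    nxt = int(nb[np.searchsorted(cw, rng.random() * cw[-1], side="right")])
                else:
                    bias = np.empty(len(nb), dtype=np.float64)
                    for i, cand in enumerate(nb):
                        cand = int(cand)
                        if cand == prev:
                            bias[i] = 1.0 / p
                        elif prev >= 0 and cand in nbr_sets[prev]:
                            bias[i] = 1.0
                        elif prev < 0:
                            bias[i] = 1.0
                        else:
                            bias[i] = 1.0 / q
                    probs = weights[cur] * bias
                    cw = np.cumsum(probs)
                    nxt = int(nb[np.searchsorted(cw, rng.random() * cw[-1], side="right")])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append(np.asarray(walk, dtype=np.int64))
    if n_isolated:
        logger.info(
            "embedding: %d walk starts skipped at isolated nodes (vectors stay at init)",
            n_isolated // walks_per_node,
        )
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers = []
    contexts = []
    for walk in walks:
        for d in range(1, window + 1):
            if len(walk) <= d:
                continue
            a, b = walk[:-d], walk[d:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _train_sgns(
    n_nodes: int,
    centers: np.ndarray,
    contexts: np.ndarray,
    dim: int,
    epochs: int,
    negative: int,
    lr0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Skip-gram with negative sampling, minibatched numpy SGD."""
    U = (rng.random((n_nodes, dim)) - 0.5) / dim  # input vectors (the embedding)
    V = np.zeros((n_nodes, dim))  # output vectors
    counts = np.bincount(centers, minlength=n_nodes).astype(np.float64)
    noise = counts**0.75
    if noise.sum() == 0:
        return U
    noise_cdf = np.cumsum(noise / noise.sum())
    n_pairs = len(centers)
    batch = 8192
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            lr = max(lr0 * (1.0 - step / max(total_steps, 1)), 1e-4)
            step += 1
            idx = order[start : start + batch]
            c = centers[idx]
            ctx = contexts[idx]
            neg = np.searchsorted(noise_cdf, rng.random((len(idx), negative)))
            u = U[c]  # (B, d)
            vpos = V[ctx]  # (B, d)
            vneg = V[neg]  # (B, k, d)
            spos = expit(np.einsum("bd,bd->b", u, vpos))
            sneg = expit(np.einsum("bd,bkd->bk", u, vneg))
            gpos = (spos - 1.0)[:, None]  # (B, 1)
            gneg = sneg[:, :, None]  # (B, k, 1)
            grad_u = gpos * vpos + np.einsum("bkd->bd", gneg * vneg)
            np.add.at(U, c, -lr * grad_u)
            np.add.at(V, ctx, -lr * gpos * u)
            np.add.at(
                V,
                neg.ravel(),
                (-lr * gneg * u[:, None, :]).reshape(-1, dim),
            )
    return U


def build_embedding(
    net: Network,
    dim: int = 128,
    walk_length: int = 80,
    walks_per_node: int = 10,
    window: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 42,
    epochs: int = 1,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> FeatureMatrix:
    """Low-dimensional node2vec embedding of the network.

    Generates ``walks_per_node`` biased random walks of ``walk_length`` from
    every non-isolated node (return parameter ``p``, in-out parameter ``q``;
    p = q = 1 reduces to unbiased first-order walks) and trains a skip-gram
    model with ``negative`` negative samples per pair on the co-occurrence
    pairs within ``window``. Fully deterministic given ``seed``: walk
    generation and the single-worker trainer draw from one seeded generator.
    """
    if dim < 2:
        raise ValueError("embedding dim must be >= 2")
    if dim >= net.n_nodes:
        warnings.warn(
            f"embedding dim {dim} >= n_nodes {net.n_nodes}: representation is "
            "no longer low-dimensional",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    walks = _generate_walks(net, walk_length, walks_per_node, p, q, rng)
    centers, contexts = _skipgram_pairs(walks, window)
    U = _train_sgns(net.n_nodes, centers, contexts, dim, epochs, negative, learning_rate, rng)
    params = {
        "kind": "embedding",
        "dim": dim,
        "walk_length": walk_length,
        "walks_per_node": walks_per_node,
        "window": window,
        "p": p,
        "q": q,
        "seed": seed,
        "epochs": epochs,
        "negative": negative,
        "learning_rate": learning_rate,
    }
    fm = FeatureMatrix(kind="embedding", values=U, params=params)
    fm.validate()
    return fm


# ---------------------------------------------------------------------------
# optional on-disk cache
# ---------------------------------------------------------------------------


def save_features(fm: FeatureMatrix, directory, name: str) -> Path:
    """Save a feature matrix as <name>.npy plus a JSON sidecar of its params."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", fm.values)
    with open(directory / f"{name}.json", "w") as fh:
        json.dump({"kind": fm.kind, "params": fm.params}, fh, sort_keys=True)
    return directory / f"{name}.npy"


def load_features(directory, name: str, expected_params: dict) -> FeatureMatrix | None:
    """Load a cached matrix only if its stored params exactly match."""
    directory = Path(directory)
    meta_path = directory / f"{name}.json"
    data_path = directory / f"{name}.npy"
    if not (meta_path.exists() and data_path.exists()):
        return None
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta["params"] != expected_params:
        return None
    return FeatureMatrix(kind=meta["kind"], values=np.load(data_path), params=meta["params"])
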