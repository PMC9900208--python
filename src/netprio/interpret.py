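"""Model interpretation: similarity to term-trained model panels and
connectivity of the top-ranked genes.

Instead of asking which terms overlap the input genes, the method asks which
term-trained classifiers *look like* the input set's classifier: every term of
a gene set collection is pushed through the identical training pipeline and
the user model is compared to the panel by cosine similarity of weight
vectors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from netprio.features import FeatureMatrix
from netprio.ingestion import GeneIndex, GeneSetCollection, Network
from netprio.labels import LabelError, select_labels
from netprio.model import ModelError, ModelResult, train

logger = logging.getLogger(__name__)

PANEL_CACHE_VERSION = 1


@dataclass
class SimilarityTable:
    """Per-term similarity of the user model to the panel, best first."""

    table: pd.DataFrame  # columns: term_id, name, similarity, rank, z_score

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


@dataclass
class Subnetwork:
    """Induced subgraph over the top-ranked genes with their annotations."""

    nodes: pd.DataFrame  # internal_id, external_id, symbol, probability, rank, known_or_novel
    edges: pd.DataFrame  # u, v (internal ids), external ids, weight

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _panel_cache_key(
    features: FeatureMatrix,
    gsc: GeneSetCollection,
    alpha: float,
    l2_strength: float,
    seed: int,
    min_positives: int,
) -> str:
    gsc_payload = sorted(
        (tid, name, sorted(members)) for tid, (name, members) in gsc.terms.items()
    )
    payload = json.dumps(
        {
            "version": PANEL_CACHE_VERSION,
            "features": features.params,
            "shape": list(features.values.shape),
            "gsc": gsc_payload,
            "alpha": alpha,
            "l2_strength": l2_strength,
            "seed": seed,
            "min_positives": min_positives,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def train_panel(
    features: FeatureMatrix,
    gsc: GeneSetCollection,
    universe: set[int],
    alpha: float = 0.05,
    l2_strength: float = 1.0,
    seed: int = 0,
    min_positives: int = 5,
    cache_dir=None,
) -> dict[str, np.ndarray]:
    """Train one model per retained term of ``gsc`` with the standard pipeline.

    Each term's members become the positives; negatives come from the same
    collection through the usual closeness screen, with the term itself always
    treated as close to its own positives (self-exclusion). Terms that cannot
    meet the positive/negative floors are skipped and logged. The resulting
    weight vectors are cached to ``cache_dir`` keyed by the feature params and
    the collection contents; a rerun with identical inputs is a pure cache hit.
    """
    key = _panel_cache_key(features, gsc, alpha, l2_strength, seed, min_positives)
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"panel_{key[:16]}.npz"
        if cache_path.exists():
            data = np.load(cache_path, allow_pickle=False)
            if str(data["key"]) == key:
                logger.info("panel cache hit (%s): %d models", cache_path.name, len(data.files) - 1)
                return {t: data[t] for t in data.files if t != "key"}

    panel: dict[str, np.ndarray] = {}
    n_skipped = 0
    for term_id in sorted(gsc.terms):
        positives = set(gsc.members(term_id))
        try:
            labels = select_labels(
                positives, gsc, universe, alpha=alpha, force_close_terms={term_id}
            )
            result = train(
                features, labels, l2_strength=l2_strength, seed=seed,
                min_positives=min_positives,
            )
        except (LabelError, ModelError) as exc:
            n_skipped += 1
            logger.info("panel term %s skipped: %s", term_id, exc)
            continue
        panel[term_id] = result.weights
    logger.info("panel: trained %d models, skipped %d terms", len(panel), n_skipped)

    if cache_path is not None and panel:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(cache_path, key=key, **panel)
    return panel


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm weight vector; similarity defined as 0", stacklevel=3)
        return 0.0
    return float(a @ b / (na * nb))


def model_similarity(
    user_weights: np.ndarray,
    panel: dict[str, np.ndarray],
    names: dict[str, str] | None = None,
    metric: str = "cosine",
) -> SimilarityTable:
    """Similarity of the user's weight vector to every panel model.

    Cosine similarity on intercept-free weight vectors by default; Pearson
    correlation available as ``metric="pearson"``. z-scores are computed over
    the panel's own similarity distribution, so a z of 2 means the term's
    model resembles the user model two panel standard deviations more than the
    average panel member does.
    """
    if not panel:
        raise ValueError("panel is empty")
    if metric not in ("cosine", "pearson"):
        raise ValueError(f"unknown similarity metric {metric!r}")
    names = names or {}
    term_ids = sorted(panel)
    sims = []
    for tid in term_ids:
        w = panel[tid]
        if w.shape != user_weights.shape:
            raise ValueError(f"panel term {tid} has weight dimension {w.shape}, "
                             f"expected {user_weights.shape}")
        if metric == "pearson":
            sims.append(_cosine(user_weights - user_weights.mean(), w - w.mean()))
        else:
            sims.append(_cosine(user_weights, w))
    sims = np.asarray(sims)
    sd = sims.std()
    z = (sims - sims.mean()) / sd if sd > 0 else np.zeros_like(sims)
    df = pd.DataFrame(
        {
            "term_id": term_ids,
            "name": [names.get(t, t) for t in term_ids],
            "similarity": sims,
            "z_score": z,
        }
    )
    df = df.sort_values(
        ["similarity", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return SimilarityTable(table=df[["term_id", "name", "similarity", "rank", "z_score"]])


def extract_subnetwork(
    net: Network, result: ModelResult, index: GeneIndex, k: int = 50
) -> Subnetwork:
    """Exact induced subgraph on the top-k ranked genes.

    Node annotations (probability, rank, known/novel) are carried over from
    the model result; the edge set is precisely the network edges with both
    endpoints in the top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, net.n_nodes)
    top = np.flatnonzero(result.ranks <= k)
    top_set = set(map(int, top))
    order = np.argsort(result.ranks[top])
    top = top[order]
    nodes = pd.DataFrame(
        {
            "internal_id": top,
            "external_id": [index.canonical[i] for i in top],
            "symbol": [index.symbols[i] for i in top],
            "probability": result.probabilities[top],
            "rank": result.ranks[top],
            "known_or_novel": np.where(result.novel_flag[top], "novel", "known"),
        }
    )
    keep = [
        (int(a), int(b), float(c))
        for a, b, c in zip(net.u, net.v, net.w)
        if int(a) in top_set and int(b) in top_set
    ]
    edges = pd.DataFrame(keep, columns=["u", "v", "weight"]).astype(
        {"u": np.int64, "v": np.int64}
    )
    edges["u_external"] = [index.canonical[i] for i in edges["u"]]
    edges["v_external"] = [index.canonical[i] for i in edges["v"]]
    return Subnetwork(nodes=nodes, edges=edges[["u", "v", "u_external", "v_external", "weight"]])


def subnetwork_to_graphml(sub: Subnetwork, path) -> None:
    """Optional GraphML export of the induced subnetwork."""
    import networkx as nx

    g = nx.Graph()
    for row in sub.nodes.itertuples(index=False):
        g.add_node(
            row.external_id,
            symbol=row.symbol,
            probability=float(row.probability),
            rank=int(row.rank),
            known_or_novel=row.known_or_novel,
        )
    for row in sub.edges.itertuples(index=False):
        g.add_edge(row.u_external, row.v_external, weight=float(row.weight))
    nx.write_graphml(g, path)
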