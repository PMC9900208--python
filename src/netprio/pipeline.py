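"""End-to-end pipeline: ingestion -> features -> labels -> model -> interpretation.

One call, :func:`run_pipeline`, reads the four inputs, runs the chosen network
representation through training and interpretation, and writes every result
table plus a reproducibility manifest into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import netprio
from netprio import features as feats
from netprio.ingestion import (
    GeneIndex,
    convert_genes,
    load_gsc,
    load_id_map,
    load_network,
    read_gene_list,
)
from netprio.interpret import extract_subnetwork, model_similarity, train_panel
from netprio.labels import select_labels
from netprio.model import cross_validate, rank_predictions, train

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("adjacency", "influence", "embedding")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized verbatim into the manifest."""

    genes: str
    network: str
    id_map: str
    background_gsc: str
    outdir: str
    interpretation_gscs: list[str] = field(default_factory=list)
    representation: str = "adjacency"
    namespace: str = "auto"
    alpha: float = 0.05
    l2_strength: float = 1.0
    k_folds: int = 5
    top_k: int = 50
    restart_prob: float = 0.85
    embedding_dim: int = 128
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    p: float = 1.0
    q: float = 1.0
    gsc_min_size: int = 3
    gsc_max_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"representation must be one of {REPRESENTATIONS}, got {self.representation!r}"
            )

    @classmethod
    def from_manifest(cls, manifest_path, outdir: str | None = None) -> "RunConfig":
        """Rebuild a config from a previous run's manifest (optionally re-homed)."""
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        cfg = manifest["config"]
        if outdir is not None:
            cfg = {**cfg, "outdir": outdir}
        return cls(**cfg)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setLevel(logging.DEBUG)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("netprio")
    root.setLevel(logging.DEBUG)
    root.addHandler(handler)
    return handler


def _build_features(config: RunConfig, net) -> feats.FeatureMatrix:
    if config.representation == "adjacency":
        return feats.build_adjacency(net)
    if config.representation == "influence":
        return feats.build_influence(net, restart_prob=config.restart_prob)
    return feats.build_embedding(
        net,
        dim=config.embedding_dim,
        walk_length=config.walk_length,
        walks_per_node=config.walks_per_node,
        window=config.window,
        p=config.p,
        q=config.q,
        seed=config.seed,
    )


def _write_labels(outdir: Path, labels, index: GeneIndex, n: int) -> None:
    rows = [
        (index.canonical[g], index.symbols[g], labels.label_of(g)) for g in range(n)
    ]
    pd.DataFrame(rows, columns=["external_id", "symbol", "label"]).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full workflow and write all result files under config.outdir.

    Writes predictions.tsv, labels.tsv, close_terms.tsv, cv_results.json,
    subnetwork_edges.tsv, subnetwork_nodes.tsv, one similarities_<name>.tsv
    per interpretation collection, run_manifest.json and run.log. Returns the
    mapping of artifact name to path.
    """
    for attr in ("genes", "network", "id_map", "background_gsc"):
        p = Path(getattr(config, attr))
        if not p.exists():
            raise FileNotFoundError(f"{attr} file not found: {p}")
    for p in config.interpretation_gscs:
        if not Path(p).exists():
            raise FileNotFoundError(f"interpretation GSC not found: {p}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        logger.info("netprio %s starting run in %s", netprio.__version__, outdir)
        index = load_id_map(config.id_map)
        report = convert_genes(read_gene_list(config.genes), index, config.namespace)
        net = load_network(config.network, index)
        gsc = load_gsc(
            config.background_gsc, index,
            min_size=config.gsc_min_size, max_size=config.gsc_max_size,
        )
        universe = set(map(int, np.unique(np.concatenate([net.u, net.v]))))
        features = _build_features(config, net)
        labels = select_labels(report.converted, gsc, universe, alpha=config.alpha)
        result = train(features, labels, l2_strength=config.l2_strength, seed=config.seed)
        cv = cross_validate(
            features, labels, k=config.k_folds, seed=config.seed,
            l2_strength=config.l2_strength,
        )

        artifacts: dict[str, Path] = {}

        pred = rank_predictions(result, index)
        artifacts["predictions"] = outdir / "predictions.tsv"
        pred.to_csv(artifacts["predictions"], sep="\t", index=False, float_format="%.10g")

        _write_labels(outdir, labels, index, net.n_nodes)
        artifacts["labels"] = outdir / "labels.tsv"

        close = pd.DataFrame(labels.close_terms, columns=["term_id", "overlap", "statistic"])
        close.insert(1, "name", [gsc.name(t) if t in gsc.terms else "" for t in close["term_id"]])
        artifacts["close_terms"] = outdir / "close_terms.tsv"
        close.to_csv(artifacts["close_terms"], sep="\t", index=False, float_format="%.10g")

        artifacts["cv_results"] = outdir / "cv_results.json"
        with open(artifacts["cv_results"], "w") as fh:
            json.dump(cv.to_dict(), fh, indent=2, sort_keys=True)

        sub = extract_subnetwork(net, result, index, k=config.top_k)
        artifacts["subnetwork_nodes"] = outdir / "subnetwork_nodes.tsv"
        artifacts["subnetwork_edges"] = outdir / "subnetwork_edges.tsv"
        sub.nodes.to_csv(artifacts["subnetwork_nodes"], sep="\t", index=False,
                         float_format="%.10g")
        sub.edges.to_csv(artifacts["subnetwork_edges"], sep="\t", index=False,
                         float_format="%.10g")

        for gsc_path in config.interpretation_gscs:
            pgsc = load_gsc(
                gsc_path, index,
                min_size=config.gsc_min_size, max_size=config.gsc_max_size,
            )
            panel = train_panel(
                features, pgsc, universe,
                alpha=config.alpha, l2_strength=config.l2_strength, seed=config.seed,
                cache_dir=outdir / "cache",
            )
            if not panel:
                logger.warning("interpretation GSC %s produced no trainable terms", gsc_path)
                continue
            simtab = model_similarity(
                result.weights, panel, names={t: pgsc.name(t) for t in pgsc.terms}
            )
            stem = Path(gsc_path).stem
            key = f"similarities_{stem}"
            artifacts[key] = outdir / f"{key}.tsv"
            simtab.table.to_csv(artifacts[key], sep="\t", index=False, float_format="%.10g")

        manifest = {
            "config": asdict(config),
            "versions": {
                "netprio": netprio.__version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "input_hashes": {
                "genes": _sha256(config.genes),
                "network": _sha256(config.network),
                "id_map": _sha256(config.id_map),
                "background_gsc": _sha256(config.background_gsc),
                "interpretation_gscs": [_sha256(p) for p in config.interpretation_gscs],
            },
            "input_genes": {
                "requested": report.n_requested,
                "converted": report.n_converted,
                "unmapped": len(report.unmapped),
                "namespace": report.namespace_used,
            },
        }
        artifacts["manifest"] = outdir / "run_manifest.json"
        with open(artifacts["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("run complete: %d artifacts in %s", len(artifacts), outdir)
        return artifacts
    finally:
        logging.getLogger("netprio").removeHandler(handler)
        handler.close()
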