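"""Synthetic benchmarks with planted structure for offline, end-to-end testing.

The central generator builds a stochastic-block-model network: ``m`` planted
modules of size ``s`` inside ``n`` nodes, dense within modules (``p_in``) and
sparse elsewhere (``p_out``). One module plays the role of the "true" gene
program; a fraction ``f`` of its genes becomes the user's input list, the rest
are held out as the genes a good method should rediscover. All on-disk
artifacts (edge list, ID map, GMT, gene list) use realistically shaped
external IDs so namespace detection is exercised, and regeneration with the
same seed is byte-for-byte identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from netprio.labels import LabelAssignment
from netprio.features import FeatureMatrix
from netprio.model import ModelResult


@dataclass
class PlantedBenchmark:
    """Ground truth and file paths for one generated benchmark."""

    paths: dict[str, Path]
    module_of: np.ndarray  # -1 for background nodes
    input_set: set[int]  # internal ids (= node indices) given to the user
    held_out: set[int]  # rest of the planted module
    params: dict = field(default_factory=dict)

    @property
    def target_module(self) -> int:
        return 0


def _entrez(i: int) -> str:
    return str(10001 + i)


def _symbol(i: int) -> str:
    return f"GENE{i:04d}"


def _ensg(i: int) -> str:
    return f"ENSG{i:011d}"


def _ensp(i: int) -> str:
    return f"ENSP{i:011d}"


def make_benchmark(
    outdir,
    n: int = 500,
    m: int = 5,
    s: int = 20,
    p_in: float = 0.3,
    p_out: float = 0.01,
    f: float = 0.5,
    noise_terms: int = 10,
    seed: int = 7,
) -> PlantedBenchmark:
    """Generate a planted-module benchmark workspace on disk.

    Writes network.tsv (unweighted edge list, Entrez IDs), id_map.tsv,
    collection.gmt (one term per planted module plus ``noise_terms`` random
    terms) and genes.txt (the input list: fraction ``f`` of module 0). All
    randomness flows from ``seed`` through a spawned seed sequence, one child
    stream per artifact, so each artifact is independently reproducible.
    """
    if m * s > n:
        raise ValueError("m * s must not exceed n")
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if not 0 < f < 1:
        raise ValueError("f must be in (0, 1)")
    n_input = round(f * s)
    if n_input < 1 or n_input >= s:
        raise ValueError(f"f={f} with module size {s} yields an empty input or hold-out set")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss_graph, ss_input, ss_noise = np.random.SeedSequence(seed).spawn(3)

    module_of = np.full(n, -1, dtype=np.int64)
    for j in range(m):
        module_of[j * s : (j + 1) * s] = j

    # SBM edge draw, vectorized over all unordered pairs
    rng = np.random.default_rng(ss_graph)
    iu, iv = np.triu_indices(n, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[iv])
    prob = np.where(same, p_in, p_out)
    keep = rng.random(len(iu)) < prob
    eu, ev = iu[keep], iv[keep]

    paths = {
        "network": outdir / "network.tsv",
        "id_map": outdir / "id_map.tsv",
        "gsc": outdir / "collection.gmt",
        "genes": outdir / "genes.txt",
    }
    with open(paths["network"], "w") as fh:
        for a, b in zip(eu, ev):
            fh.write(f"{_entrez(a)}\t{_entrez(b)}\n")

    with open(paths["id_map"], "w") as fh:
        fh.write("entrez\tsymbol\tensembl_gene\tensembl_protein\n")
        for i in range(n):
            ensp = "" if i % 17 == 16 else _ensp(i)  # partial protein namespace
            fh.write(f"{_entrez(i)}\t{_symbol(i)}\t{_ensg(i)}\t{ensp}\n")

    rng_noise = np.random.default_rng(ss_noise)
    with open(paths["gsc"], "w") as fh:
        for j in range(m):
            members = "\t".join(_entrez(i) for i in range(j * s, (j + 1) * s))
            fh.write(f"MODULE_{j}\tplanted module {j}\t{members}\n")
        for t in range(noise_terms):
            size = int(rng_noise.integers(10, 31))
            picks = np.sort(rng_noise.choice(n, size=size, replace=False))
            members = "\t".join(_entrez(i) for i in picks)
            fh.write(f"NOISE_{t:02d}\trandom term {t}\t{members}\n")

    rng_input = np.random.default_rng(ss_input)
    picks = np.sort(rng_input.choice(s, size=n_input, replace=False))
    input_set = {int(i) for i in picks}
    with open(paths["genes"], "w") as fh:
        for i in sorted(input_set):
            fh.write(f"{_entrez(i)}\n")

    module0 = set(range(s))
    return PlantedBenchmark(
        paths=paths,
        module_of=module_of,
        input_set=input_set,
        held_out=module0 - input_set,
        params={
            "n": n, "m": m, "s": s, "p_in": p_in, "p_out": p_out,
            "f": f, "noise_terms": noise_terms, "seed": seed,
        },
    )


def expected_recovery(benchmark: PlantedBenchmark, result: ModelResult) -> float:
    """Fraction of held-out module genes found in the top-s novel predictions.

    The top s (module size) genes by probability among the novel predictions
    (genes not in the input set) are compared to the held-out module members;
    1.0 means the method rediscovered the entire hidden half of the module.
    """
    s = benchmark.params["s"]
    novel = np.flatnonzero(result.novel_flag)
    order = novel[np.lexsort((novel, -result.probabilities[novel]))]
    top_novel = set(map(int, order[:s]))
    if not benchmark.held_out:
        raise ValueError("benchmark has no held-out genes")
    return len(top_novel & benchmark.held_out) / len(benchmark.held_out)


def make_separable_features(
    n_pos: int = 20,
    n_neg: int = 40,
    dim: int = 5,
    gap: float = 10.0,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureMatrix, LabelAssignment]:
    """Perfectly separable toy: positives and negatives split by one feature.

    Feature 0 is ``+gap`` for positives and ``-gap`` for negatives plus tiny
    Gaussian noise; remaining dimensions are pure noise. Used for ceiling
    tests where the classifier must reach auROC and auPRC of exactly 1.
    """
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.normal(0.0, 1.0, size=(n, dim))
    X[:n_pos, 0] = gap + noise * rng.normal(size=n_pos)
    X[n_pos:, 0] = -gap + noise * rng.normal(size=n_neg)
    fm = FeatureMatrix(kind="embedding", values=X, params={"kind": "synthetic_separable"})
    labels = LabelAssignment(positives=set(range(n_pos)), negatives=set(range(n_pos, n)))
    return fm, labels
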