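"""Reading and validating gene lists, ID maps, networks and gene set collections.

Everything downstream works on a dense internal gene index (0..n-1) defined by
the ID-mapping table. This module owns the conversion between the four external
ID namespaces (Entrez, gene symbol, Ensembl gene, Ensembl protein) and that
internal index, plus the parsers for edge-list networks and GMT collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized namespaces, in the fixed priority order used for tie-breaking.
NAMESPACES = ("entrez", "symbol", "ensembl_gene", "ensembl_protein")


class IngestionError(ValueError):
    """Fatal problem with an input file or gene list."""


def _norm_entrez(raw: str) -> str:
    return raw.strip()


def _norm_symbol(raw: str) -> str:
    # symbols match case-insensitively after whitespace stripping
    return raw.strip().casefold()


def _norm_ensembl(raw: str) -> str:
    # Ensembl version suffixes (".N") are stripped before lookup
    s = raw.strip()
    head, dot, tail = s.partition(".")
    if dot and tail.isdigit():
        return head
    return s


_NORMALIZERS = {
    "entrez": _norm_entrez,
    "symbol": _norm_symbol,
    "ensembl_gene": _norm_ensembl,
    "ensembl_protein": _norm_ensembl,
}


@dataclass
class GeneIndex:
    """Bidirectional map between external gene IDs and dense internal indices.

    ``maps[namespace]`` sends a normalized external string to an internal id.
    Namespace maps may be partial and many-to-one (synonyms); when two rows of
    the ID table claim the same external ID the first-listed row wins, so the
    resolved mapping is never one-to-many. ``canonical`` gives one external ID
    per internal id (Entrez preferred, then symbol, then Ensembl gene/protein),
    and ``symbols`` keeps a display symbol per gene for output tables.
    """

    n_genes: int
    maps: dict[str, dict[str, int]]
    canonical: list[str]
    symbols: list[str]

    def resolve(self, raw: str, namespace: str) -> int | None:
        """Return the internal id for ``raw`` in ``namespace``, or None."""
        return self.maps[namespace].get(_NORMALIZERS[namespace](raw))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_genes


def load_id_map(path) -> GeneIndex:
    """Load a TSV ID-mapping table into a :class:`GeneIndex`.

    The file must have a header with columns ``entrez``, ``symbol``,
    ``ensembl_gene``, ``ensembl_protein``; one gene per row; empty cell means
    the gene has no ID in that namespace. Internal ids are assigned in row
    order. Duplicate external IDs resolve to the first-listed gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in NAMESPACES if c not in df.columns]
    if missing:
        raise IngestionError(f"ID map {path} lacks required columns: {missing}")
    n = len(df)
    maps: dict[str, dict[str, int]] = {ns: {} for ns in NAMESPACES}
    canonical: list[str] = []
    symbols: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        cano = None
        for ns in NAMESPACES:
            raw = getattr(row, ns)
            if not raw or not raw.strip():
                continue
            key = _NORMALIZERS[ns](raw)
            if key not in maps[ns]:  # first-listed wins on synonym collisions
                maps[ns][key] = i
            if cano is None:
                cano = raw.strip()
        if cano is None:
            raise IngestionError(f"ID map row {i + 2}: gene has no ID in any namespace")
        canonical.append(cano)
        sym = getattr(row, "symbol").strip()
        symbols.append(sym if sym else cano)
    return GeneIndex(n_genes=n, maps=maps, canonical=canonical, symbols=symbols)


def detect_namespace(ids: list[str], index: GeneIndex) -> str:
    """Pick the namespace in which the largest fraction of ``ids`` resolves.

    Ties break by the fixed order entrez, symbol, ensembl_gene,
    ensembl_protein. Raises :class:`IngestionError` if no namespace resolves
    any of the ids.
    """
    if not ids:
        raise IngestionError("cannot detect namespace of an empty gene list")
    fractions = {}
    for ns in NAMESPACES:
        hits = sum(1 for raw in ids if index.resolve(raw, ns) is not None)
        fractions[ns] = hits / len(ids)
    best = max(NAMESPACES, key=lambda ns: fractions[ns])  # max is stable: tie -> order
    if fractions[best] == 0.0:
        sample = ", ".join(list(dict.fromkeys(ids))[:5])
        raise IngestionError(
            f"no namespace matches the input gene list (sample ids: {sample})"
        )
    logger.debug("namespace detection fractions: %s -> %s", fractions, best)
    return best


@dataclass
class InputGeneReport:
    """Outcome of converting a raw gene list to internal ids."""

    requested: list[str]
    converted: set[int]
    unmapped: list[str]
    namespace_used: str

    @property
    def n_requested(self) -> int:
        return len(self.requested)

    @property
    def n_converted(self) -> int:
        return len(self.converted)


def convert_genes(
    ids: list[str], index: GeneIndex, namespace: str = "auto"
) -> InputGeneReport:
    """Convert raw gene IDs to internal ids, recording what failed to map.

    ``namespace`` may be one of the four namespaces or ``"auto"`` to detect it.
    Duplicated inputs collapse to a single internal id; unmapped IDs are kept
    in input order. Raises if nothing converts.
    """
    ids = [s.strip() for s in ids if s.strip()]
    if namespace == "auto":
        namespace = detect_namespace(ids, index)
    elif namespace not in NAMESPACES:
        raise IngestionError(f"unknown namespace {namespace!r}")
    converted: set[int] = set()
    unmapped: list[str] = []
    for raw in ids:
        internal = index.resolve(raw, namespace)
        if internal is None:
            unmapped.append(raw)
        else:
            converted.add(internal)
    if not converted:
        raise IngestionError("empty positive set: no input gene could be converted")
    if unmapped:
        logger.info("%d of %d input genes could not be mapped", len(unmapped), len(ids))
    return InputGeneReport(
        requested=ids, converted=converted, unmapped=unmapped, namespace_used=namespace
    )


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one ID per line; '#' lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out


@dataclass
class Network:
    """Undirected weighted network over internal gene ids.

    Edges are stored once per unordered pair with ``u < v``; weights are
    strictly positive. ``n_nodes`` always equals the size of the gene index so
    genes with no interactions are isolated nodes, not missing nodes.
    """

    n_nodes: int
    u: np.ndarray  # int64
    v: np.ndarray  # int64
    w: np.ndarray  # float64, all > 0
    weighted: bool
    n_self_loops_dropped: int = 0
    n_unmapped_rows_dropped: int = 0
    n_duplicates_merged: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.u)

    def degrees(self) -> np.ndarray:
        """Unweighted degree of every node."""
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.u, 1)
        np.add.at(d, self.v, 1)
        return d

    def edge_set(self) -> set[tuple[int, int, float]]:
        return {
            (int(a), int(b), float(c)) for a, b, c in zip(self.u, self.v, self.w)
        }

    def neighbors(self) -> list[np.ndarray]:
        """Adjacency lists (neighbor arrays) for every node."""
        nbr: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in zip(self.u, self.v):
            nbr[a].append(int(b))
            nbr[b].append(int(a))
        return [np.asarray(sorted(x), dtype=np.int64) for x in nbr]

    def to_tsv(self, path, index: GeneIndex) -> None:
        """Write the edge list with canonical external IDs (round-trippable)."""
        with open(path, "w") as fh:
            for a, b, c in zip(self.u, self.v, self.w):
                fh.write(f"{index.canonical[a]}\t{index.canonical[b]}\t{c:.17g}\n")


def load_network(path, index: GeneIndex, namespace: str = "auto") -> Network:
    """Load an edge-list TSV into a :class:`Network`.

    Rows have 2 or 3 whitespace/tab-separated columns: node1, node2[, weight];
    '#' comment lines are skipped; a missing weight column means weight 1.0.
    Self-loops are dropped, duplicate unordered pairs merge by keeping the
    maximum weight, and rows naming genes absent from the index are dropped
    (counted and logged). Non-numeric or non-positive weights are fatal.
    """
    rows: list[tuple[str, str, str | None, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t") if "\t" in s else s.split()
            if len(parts) < 2 or len(parts) > 3:
                raise IngestionError(
                    f"{path} line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            rows.append((parts[0], parts[1], parts[2] if len(parts) == 3 else None, lineno))
    if not rows:
        raise IngestionError(f"network file {path} contains no edges")

    if namespace == "auto":
        tokens = [r[0] for r in rows] + [r[1] for r in rows]
        namespace = detect_namespace(tokens, index)

    weighted = any(r[2] is not None for r in rows)
    best: dict[tuple[int, int], float] = {}
    n_self = n_unmapped = n_dup = 0
    for raw_u, raw_v, raw_w, lineno in rows:
        if raw_w is None:
            weight = 1.0
        else:
            try:
                weight = float(raw_w)
            except ValueError:
                raise IngestionError(
                    f"{path} line {lineno}: non-numeric weight {raw_w!r}"
                ) from None
            if not np.isfinite(weight) or weight <= 0:
                raise IngestionError(
                    f"{path} line {lineno}: weight must be positive, got {raw_w}"
                )
        a = index.resolve(raw_u, namespace)
        b = index.resolve(raw_v, namespace)
        if a is None or b is None:
            n_unmapped += 1
            continue
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in best:
            n_dup += 1
            best[key] = max(best[key], weight)
        else:
            best[key] = weight

    if n_unmapped or n_self or n_dup:
        logger.info(
            "network %s: dropped %d unmappable rows, %d self-loops; merged %d duplicate pairs",
            path, n_unmapped, n_self, n_dup,
        )
    if not best:
        raise IngestionError(f"network file {path}: no usable edges after cleaning")
    pairs = sorted(best)
    u = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    v = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    w = np.fromiter((best[p] for p in pairs), dtype=np.float64, count=len(pairs))
    return Network(
        n_nodes=index.n_genes,
        u=u,
        v=v,
        w=w,
        weighted=weighted,
        n_self_loops_dropped=n_self,
        n_unmapped_rows_dropped=n_unmapped,
        n_duplicates_merged=n_dup,
    )


@dataclass
class GeneSetCollection:
    """Named gene sets (terms) over internal ids, size-filtered at load time."""

    terms: dict[str, tuple[str, frozenset[int]]] = field(default_factory=dict)
    min_size: int = 3
    max_size: int = 200

    def members(self, term_id: str) -> frozenset[int]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def all_annotated(self) -> set[int]:
        """Union of every retained term's members."""
        out: set[int] = set()
        for _, members in self.terms.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.terms)


def load_gsc(
    path,
    index: GeneIndex,
    min_size: int = 3,
    max_size: int = 200,
    namespace: str = "auto",
) -> GeneSetCollection:
    """Load a GMT file (term_id TAB description TAB member...) into a collection.

    Members that do not map to the index are dropped; terms whose mapped size
    falls outside [min_size, max_size] are discarded. A line with fewer than
    three fields is fatal with its line number.
    """
    raw_terms: list[tuple[str, str, list[str], int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) < 3:
                raise IngestionError(
                    f"{path} line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            term_id, name, members = parts[0], parts[1], [m for m in parts[2:] if m.strip()]
            raw_terms.append((term_id, name, members, lineno))
    gsc = GeneSetCollection(min_size=min_size, max_size=max_size)
    if not raw_terms:
        logger.warning("GSC file %s is empty; collection has no terms", path)
        return gsc

    if namespace == "auto":
        pool = [m for _, _, members, _ in raw_terms for m in members]
        if not pool:
            logger.warning("GSC file %s has no members in any term", path)
            return gsc
        namespace = detect_namespace(pool, index)

    n_dropped_members = n_dropped_terms = 0
    for term_id, name, members, _lineno in raw_terms:
        mapped = set()
        for raw in members:
            internal = index.resolve(raw, namespace)
            if internal is None:
                n_dropped_members += 1
            else:
                mapped.add(internal)
        if min_size <= len(mapped) <= max_size:
            gsc.terms[term_id] = (name, frozenset(mapped))
        else:
            n_dropped_terms += 1
    logger.info(
        "GSC %s: retained %d/%d terms (size bounds [%d, %d]); %d unmappable members dropped",
        path, len(gsc), len(raw_terms), min_size, max_size, n_dropped_members,
    )
    return gsc
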