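"""Positive/negative/excluded training labels from a background gene set collection.

The labeling rule: a gene is a candidate negative if it is annotated to at
least one term of the background collection; it is excluded (neither positive
nor negative) if any of its terms is statistically "close" to the positive
set, since such genes are plausible unlabeled positives. Genes annotated
nowhere stay unlabeled and are only scored at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from netprio.ingestion import GeneSetCollection

logger = logging.getLogger(__name__)

MIN_NEGATIVES = 10


class LabelError(ValueError):
    """Fatal labeling problem (e.g. too few negatives to train)."""


@dataclass
class LabelAssignment:
    """Disjoint positive/negative/excluded sets over internal ids.

    ``close_terms`` records the background terms judged close to the positive
    set, as (term_id, overlap, statistic) tuples. Genes outside every
    background term are implicitly unlabeled.
    """

    positives: set[int]
    negatives: set[int]
    excluded: set[int] = field(default_factory=set)
    close_terms: list[tuple[str, int, float]] = field(default_factory=list)
    n_positives_outside_network: int = 0

    def __post_init__(self) -> None:
        if self.positives & self.negatives or self.positives & self.excluded or (
            self.negatives & self.excluded
        ):
            raise LabelError("positives, negatives and excluded must be disjoint")

    def label_of(self, gene: int) -> str:
        """P, N, E or U for a single internal id."""
        if gene in self.positives:
            return "P"
        if gene in self.negatives:
            return "N"
        if gene in self.excluded:
            return "E"
        return "U"


def term_closeness(positives: set[int], term: set[int], universe_size: int) -> float:
    """One-sided hypergeometric tail probability of the observed overlap.

    Returns P[X >= |positives ∩ term|] where X is the overlap of a uniformly
    random draw of |positives| genes from a universe containing |term|
    annotated genes — the standard overrepresentation tail. Small values mean
    the term shares more genes with the positive set than chance predicts.
    Empty term or empty positives return 1.0 by convention.
    """
    if not positives or not term:
        return 1.0
    if universe_size < len(positives | term):
        raise ValueError("universe_size smaller than the union of the two sets")
    overlap = len(positives & term)
    # sf(k-1) = P[X >= k]
    return float(hypergeom.sf(overlap - 1, universe_size, len(term), len(positives)))


def _jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def select_labels(
    positives: set[int],
    gsc: GeneSetCollection,
    universe: set[int],
    alpha: float = 0.05,
    method: str = "hypergeometric",
    jaccard_threshold: float = 0.05,
    force_close_terms: set[str] | None = None,
    min_negatives: int = MIN_NEGATIVES,
) -> LabelAssignment:
    """Partition background-annotated genes into negatives and exclusions.

    The closeness screen runs per term against the positive set restricted to
    ``universe`` (the network's genes — features only exist there). With the
    default hypergeometric method a term is close when its overlap tail
    probability is below ``alpha``; the alternative Jaccard mode flags terms
    with Jaccard index >= ``jaccard_threshold``. ``force_close_terms`` marks
    terms as close unconditionally (used when a term's own members are the
    positives). No multiple-testing correction is applied: the screen errs
    toward exclusion rather than label contamination.
    """
    if method not in ("hypergeometric", "jaccard"):
        raise ValueError(f"unknown closeness method {method!r}")
    pos_in_net = positives & universe
    n_outside = len(positives) - len(pos_in_net)
    if n_outside:
        logger.info("%d positives are outside the network and dropped from training", n_outside)
    if not pos_in_net:
        raise LabelError("no positive gene is present in the network")
    force_close_terms = force_close_terms or set()

    close_terms: list[tuple[str, int, float]] = []
    excluded: set[int] = set()
    annotated: set[int] = set()
    for term_id, (_name, members) in gsc.terms.items():
        members_in_net = set(members) & universe
        annotated |= members_in_net
        overlap = len(pos_in_net & members_in_net)
        if method == "hypergeometric":
            stat = term_closeness(pos_in_net, members_in_net, len(universe))
            is_close = stat < alpha
        else:
            stat = _jaccard(pos_in_net, members_in_net)
            is_close = stat >= jaccard_threshold
        if term_id in force_close_terms:
            is_close = True
        if is_close:
            close_terms.append((term_id, overlap, stat))
            excluded |= members_in_net
    excluded -= pos_in_net
    negatives = annotated - excluded - pos_in_net
    if len(negatives) < min_negatives:
        raise LabelError(
            f"insufficient negatives ({len(negatives)} < {min_negatives}); "
            "use a larger background collection or a smaller alpha"
        )
    logger.info(
        "labels: %d positives, %d negatives, %d excluded (%d close terms)",
        len(pos_in_net), len(negatives), len(excluded), len(close_terms),
    )
    return LabelAssignment(
        positives=pos_in_net,
        negatives=negatives,
        excluded=excluded,
        close_terms=close_terms,
        n_positives_outside_network=n_outside,
    )
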