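"""Building the balanced labelled pair set.

Positives come from a curated answer set, optionally boosted by expanding
seed genes through their interactome neighbourhood; negatives are sampled
uniformly from non-interacting gene pairs to match the positive count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome", "LabeledPairSet", "canonical_pair",
    "filter_by_confidence", "expand_positives", "sample_negatives",
    "build_labeled_set", "read_edge_list", "write_edge_list",
    "read_gene_list",
]


def canonical_pair(a: str, b: str) -> tuple:
    """Unordered pair as a sorted 2-tuple of non-empty gene ids."""
    a, b = str(a), str(b)
    if not a or not b:
        raise ValueError("empty gene identifier")
    if a == b:
        raise ValueError(f"self-loop {a!r}")
    return (a, b) if a < b else (b, a)


class Interactome:
    """Undirected gene graph with optional per-edge confidence scores.

    Edges are stored once, canonically ordered; self-loops are rejected.
    """

    def __init__(self, edges=()):
        self._conf: dict = {}
        self._adj: dict = {}
        for e in edges:
            if len(e) == 3:
                self.add_edge(e[0], e[1], e[2])
            else:
                self.add_edge(e[0], e[1])

    def add_edge(self, a: str, b: str, confidence=None) -> None:
        pair = canonical_pair(a, b)
        self._conf[pair] = None if confidence is None else float(confidence)
        self._adj.setdefault(pair[0], set()).add(pair[1])
        self._adj.setdefault(pair[1], set()).add(pair[0])

    def __contains__(self, pair) -> bool:
        a, b = pair
        if a == b:
            return False
        return canonical_pair(a, b) in self._conf

    def __len__(self) -> int:
        return len(self._conf)

    def edges(self) -> list:
        return sorted(self._conf)

    def confidence(self, pair):
        return self._conf[canonical_pair(*pair)]

    def genes(self) -> set:
        return set(self._adj)

    def neighbors(self, gene: str) -> set:
        return set(self._adj.get(str(gene), ()))

    def degree(self, gene: str) -> int:
        return len(self._adj.get(str(gene), ()))


@dataclass
class LabeledPairSet:
    """Balanced positive/negative pair collection with per-pair provenance."""

    positives: set
    negatives: set
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    @property
    def pairs(self) -> list:
        """All pairs, positives first, each side sorted for determinism."""
        return sorted(self.positives) + sorted(self.negatives)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives), dtype=int)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\tgene_a\tgene_b\tlabel\tprovenance\n")
            for pair, label in zip(self.pairs, self.labels):
                a, b = pair
                fh.write(f"{a}|{b}\t{a}\t{b}\t{label}\t"
                         f"{self.provenance.get(pair, '')}\n")


def filter_by_confidence(net: Interactome, top_fraction: float) -> Interactome:
    """Keep the ceil(top_fraction * |edges|) highest-confidence edges.

    Ties at the cutoff are broken by lexicographic pair id (deterministic).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if top_fraction == 1.0:
        return Interactome((a, b, net._conf[(a, b)]) for a, b in net.edges())
    missing = [p for p in net.edges() if net._conf[p] is None]
    if missing:
        raise ValueError(
            f"{len(missing)} edge(s) lack confidence scores; cannot filter"
        )
    keep = math.ceil(top_fraction * len(net))
    ranked = sorted(net.edges(), key=lambda p: (-net._conf[p], p))
    return Interactome((a, b, net._conf[(a, b)]) for a, b in ranked[:keep])


def expand_positives(answer_set, net: Interactome, seeds, k: int = 1,
                     induced: bool = False) -> set:
    """Boost the answer set with interactome edges around seed genes.

    The seed neighbourhood is grown for `k` hops (default: first
    neighbours). By default every interactome edge with at least one
    endpoint in the neighbourhood is added; with ``induced=True`` both
    endpoints must lie in it.
    """
    positives = {canonical_pair(*p) for p in answer_set}
    reach = {str(s) for s in seeds}
    frontier = set(reach)
    for _ in range(k):
        frontier = {n for g in frontier for n in net.neighbors(g)} - reach
        reach |= frontier
    if not reach:
        return positives
    for a, b in net.edges():
        if induced:
            if a in reach and b in reach:
                positives.add((a, b))
        elif a in reach or b in reach:
            positives.add((a, b))
    return positives


def sample_negatives(positives, gene_universe, net: Interactome, n: int,
                     rng_seed: int) -> set:
    """Draw `n` distinct unordered pairs uniformly from the universe,
    excluding positives and all interactome edges. Deterministic given
    `rng_seed`; raises with counts if too few eligible pairs exist."""
    genes = sorted(str(g) for g in set(gene_universe))
    u = len(genes)
    total = u * (u - 1) // 2
    universe = set(genes)
    excluded = {canonical_pair(*p) for p in positives
                if p[0] in universe and p[1] in universe}
    excluded |= {e for e in net.edges() if e[0] in universe and e[1] in universe}
    eligible = total - len(excluded)
    if n > eligible:
        raise ValueError(
            f"cannot sample {n} negatives: only {eligible} eligible pairs "
            f"({total} total, {len(excluded)} excluded)"
        )
    rng = np.random.default_rng(rng_seed)
    result: set = set()
    if n > eligible // 2 or total <= 200_000:
        # dense regime: enumerate eligible pairs and choose directly
        pool = [(genes[i], genes[j]) for i in range(u) for j in range(i + 1, u)
                if (genes[i], genes[j]) not in excluded]
        idx = rng.choice(len(pool), size=n, replace=False)
        result = {pool[i] for i in idx}
    else:
        while len(result) < n:
            i, j = rng.integers(0, u, size=2)
            if i == j:
                continue
            pair = canonical_pair(genes[i], genes[j])
            if pair in excluded or pair in result:
                continue
            result.add(pair)
    return result


def build_labeled_set(answer_set, net: Interactome, seeds,
                      ds: ExpressionDataset, rng_seed: int, *,
                      k: int = 1, induced: bool = False,
                      include_net_edges: bool = True,
                      exclude_net_negatives: bool = True) -> LabeledPairSet:
    """Assemble the balanced labelled pair set for training.

    With seeds, positives = answer set boosted by `expand_positives`;
    without, positives = answer set plus (by default) all interactome
    edges. Pairs whose genes are absent from the expression dataset are
    dropped (logged). Negatives are sampled to match the final positive
    count; by default they also avoid every interactome edge.
    """
    answer = {canonical_pair(*p) for p in answer_set}
    if seeds:
        positives = expand_positives(answer, net, seeds, k=k, induced=induced)
    elif include_net_edges:
        positives = answer | set(net.edges())
    else:
        positives = set(answer)

    universe = set(ds.gene_ids)
    kept = {p for p in positives if p[0] in universe and p[1] in universe}
    dropped = len(positives) - len(kept)
    if dropped:
        logger.info("dropped %d positive pair(s) with genes absent from the "
                    "expression dataset", dropped)
    if not kept:
        raise ValueError("no positive pairs remain after restricting to the "
                         "expression dataset's genes")

    neg_net = net if exclude_net_negatives else Interactome()
    negatives = sample_negatives(kept, universe, neg_net, len(kept), rng_seed)

    provenance = {}
    for p in kept:
        provenance[p] = "answer_set" if p in answer else "seed_expansion"
    for p in negatives:
        provenance[p] = "random_negative"
    return LabeledPairSet(positives=kept, negatives=negatives, provenance=provenance)


# ---------------------------------------------------------------------------
# file formats: 2/3-column edge TSVs and one-gene-per-line lists

def read_edge_list(path, scored: bool = False):
    """Read a TSV edge list. Returns an `Interactome` when ``scored`` or a
    third column is present; otherwise a set of canonical pairs."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("gene_a", "gene_id"):
                continue
            rows.append(parts)
    has_conf = scored or any(len(r) >= 3 for r in rows)
    if has_conf:
        net = Interactome()
        for r in rows:
            conf = float(r[2]) if len(r) >= 3 else None
            net.add_edge(r[0], r[1], conf)
        return net
    return {canonical_pair(r[0], r[1]) for r in rows}


def write_edge_list(path, edges, confidences=None) -> None:
    edges = sorted(canonical_pair(*e) for e in edges)
    with open(path, "w") as fh:
        for a, b in edges:
            if confidences is not None and (a, b) in confidences:
                fh.write(f"{a}\t{b}\t{confidences[(a, b)]:.6g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}
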