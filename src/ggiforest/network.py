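"""Applying a trained model to a new dataset and analysing the predicted
interaction network (hub extraction, correlation audit)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .features import GenePair, feature_matrix, mutual_information, pcc
from .forest import TrainedForest, predict
from .labeling import Interactome, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "PredictedNetwork", "HubSubnetwork",
    "candidate_pairs", "classify_network", "hub_subnetwork",
    "correlation_audit", "write_network", "read_network",
]


@dataclass
class PredictedNetwork:
    """Predicted-positive pairs with their vote scores (> 0.5 each)."""

    edges: dict                      # canonical pair -> score
    seed_genes: set = field(default_factory=set)

    @property
    def nodes(self) -> set:
        return {g for pair in self.edges for g in pair}

    def degree(self, gene: str) -> int:
        return sum(1 for pair in self.edges if gene in pair)

    def degrees(self) -> dict:
        deg: dict = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


@dataclass
class HubSubnetwork:
    """Top-degree hubs plus their neighbourhood in the predicted network."""

    hubs: list                       # ordered by (degree desc, id)
    nodes: set
    edges: dict                      # canonical pair -> score
    full_degrees: dict               # node -> degree in the FULL network


def candidate_pairs(ds: ExpressionDataset, net: Interactome) -> list:
    """All interactome edges whose two genes both occur in the dataset,
    materialised as GenePairs with per-class expression lists."""
    universe = set(ds.gene_ids)
    out = [GenePair.from_dataset(ds, a, b)
           for a, b in net.edges() if a in universe and b in universe]
    if not out:
        raise ValueError(
            "no interactome edge maps onto the expression dataset; check "
            "that gene identifiers use the same namespace"
        )
    return out


def classify_network(model: TrainedForest, candidates, bins: int = 10,
                     rng_seed: int = 0, seed_genes=()) -> PredictedNetwork:
    """Score candidate pairs and keep the predicted-positive ones."""
    X, _ = feature_matrix(candidates, bins=bins, rng_seed=rng_seed)
    labels, scores = predict(model, X)
    edges = {canonical_pair(p.gene_a, p.gene_b): float(s)
             for p, l, s in zip(candidates, labels, scores) if l == 1}
    if not edges:
        logger.warning("classifier predicted no positive pair; network is empty")
    logger.info("predicted network: %d nodes, %d edges",
                len({g for e in edges for g in e}), len(edges))
    return PredictedNetwork(edges=edges,
                            seed_genes={str(s) for s in seed_genes})


def hub_subnetwork(net: PredictedNetwork, top_k: int = 20, *,
                   induced: bool = False) -> HubSubnetwork:
    """Extract the top-`top_k` degree hubs and their neighbourhood.

    Nodes are ranked by full-network degree, ties broken lexicographically.
    The default subnetwork keeps every predicted edge touching at least one
    hub (so hub degrees are preserved); ``induced=True`` keeps hub-hub
    edges only.
    """
    if not net.edges:
        raise ValueError("predicted network is empty")
    deg = net.degrees()
    ranked = sorted(deg, key=lambda g: (-deg[g], g))
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds %d nodes; using all nodes",
                       top_k, len(ranked))
        top_k = len(ranked)
    hubs = ranked[:top_k]
    hub_set = set(hubs)
    if induced:
        edges = {e: s for e, s in net.edges.items()
                 if e[0] in hub_set and e[1] in hub_set}
    else:
        edges = {e: s for e, s in net.edges.items()
                 if e[0] in hub_set or e[1] in hub_set}
    nodes = hub_set | {g for e in edges for g in e}
    return HubSubnetwork(hubs=hubs, nodes=nodes, edges=edges, full_degrees=deg)


def correlation_audit(net: PredictedNetwork, answer_set,
                      ds: ExpressionDataset, bins: int = 10) -> pd.DataFrame:
    """Per-class PCC and MI summary for predicted edges absent from the
    answer set (the novel predictions).

    Returns a tidy table (measure, class_label, n_pairs, mean, sd); sd uses
    ddof=1 and is NaN for fewer than two pairs.
    """
    answer = {canonical_pair(*p) for p in answer_set}
    novel = sorted(e for e in net.edges if e not in answer)
    vals = {("PCC", 0): [], ("PCC", 1): [], ("MI", 0): [], ("MI", 1): []}
    for a, b in novel:
        pair = GenePair.from_dataset(ds, a, b)
        vals[("PCC", 0)].append(pcc(pair.e_a_l0, pair.e_b_l0))
        vals[("PCC", 1)].append(pcc(pair.e_a_l1, pair.e_b_l1))
        vals[("MI", 0)].append(mutual_information(pair.e_a_l0, pair.e_b_l0, bins))
        vals[("MI", 1)].append(mutual_information(pair.e_a_l1, pair.e_b_l1, bins))
    rows = []
    for (measure, cls), v in vals.items():
        arr = np.asarray(v, dtype=float)
        rows.append({
            "measure": measure,
            "class_label": cls,
            "n_pairs": len(arr),
            "mean": float(arr.mean()) if len(arr) else np.nan,
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def write_network(net: PredictedNetwork, tsv_path, sif_path=None) -> None:
    """Edge list as TSV (gene_a, gene_b, score) and optionally SIF."""
    with open(tsv_path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for (a, b) in sorted(net.edges):
            fh.write(f"{a}\t{b}\t{net.edges[(a, b)]:.6g}\n")
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for (a, b) in sorted(net.edges):
                fh.write(f"{a}\tggi\t{b}\n")


def read_network(tsv_path, seed_genes=()) -> PredictedNetwork:
    edges = {}
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            a, b, s = line.split("\t")
            edges[canonical_pair(a, b)] = float(s)
    return PredictedNetwork(edges=edges, seed_genes={str(s) for s in seed_genes})


def write_subnetwork_report(sub: HubSubnetwork, net: PredictedNetwork, path) -> None:
    """Node table: node, full-network degree, is_hub, is_seed."""
    hub_set = set(sub.hubs)
    with open(path, "w") as fh:
        fh.write("node\tdegree\tis_hub\tis_seed\n")
        for node in sorted(sub.nodes):
            fh.write(f"{node}\t{sub.full_degrees.get(node, 0)}\t"
                     f"{int(node in hub_set)}\t{int(node in net.seed_genes)}\n")
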