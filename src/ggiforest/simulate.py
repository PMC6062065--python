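"""Synthetic two-class benchmark generator.

Produces an expression matrix, a scale-free interactome, seed genes, an
answer set and a planted-pair truth table with the statistical regime the
classifier targets: "disease" gene pairs whose class-1 marginals shift in
mean and inflate in variance (with extra per-sample heterogeneity noise)
while their pairwise linear correlation stays weak in BOTH classes — the
setting where a plain correlation threshold fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionDataset, write_expression
from .labeling import Interactome, canonical_pair, write_edge_list

__all__ = ["SimulationConfig", "SimulatedData", "simulate_dataset", "write_fixtures"]

_MAX_PAIR_RETRIES = 1000


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_samples_class0: int = 60
    n_samples_class1: int = 60
    n_disease_pairs: int = 100
    heterogeneity_sd: float = 1.0
    mean_shift: float = 0.8
    sd_inflation: float = 1.5
    max_abs_pcc: float = 0.3
    interactome_degree_param: int = 2
    seed_fraction: float = 0.25      # fraction of disease genes used as seeds
    answer_fraction: float = 0.5     # fraction of planted pairs in the answer set
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_samples_class0, self.n_samples_class1) <= 0:
            raise ValueError("counts must be positive")
        if self.n_disease_pairs < 0:
            raise ValueError("n_disease_pairs must be >= 0")
        if 2 * self.n_disease_pairs > self.n_genes:
            raise ValueError("not enough genes for the requested disease pairs")
        if not 0 <= self.max_abs_pcc < 1:
            raise ValueError("max_abs_pcc must be in [0, 1)")
        if min(self.n_samples_class0, self.n_samples_class1) < 4:
            raise ValueError("each class needs at least 4 samples")
        if self.interactome_degree_param < 1:
            raise ValueError("interactome_degree_param must be >= 1")


@dataclass
class SimulatedData:
    dataset: ExpressionDataset        # un-normalised
    interactome: Interactome
    seeds: set
    answer_set: set
    truth: pd.DataFrame               # planted pairs: gene_a, gene_b, per-class PCC

    @property
    def truth_pairs(self) -> set:
        return {canonical_pair(a, b)
                for a, b in zip(self.truth["gene_a"], self.truth["gene_b"])}


def _gene_names(n: int):
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _planted_pair_values(rng, cfg: SimulationConfig):
    """Class-0 and class-1 rows for the two genes of one disease pair,
    rejection-sampled until |PCC| < max_abs_pcc within both classes."""
    n0, n1 = cfg.n_samples_class0, cfg.n_samples_class1
    for _ in range(_MAX_PAIR_RETRIES):
        rows = []
        for _g in range(2):
            l0 = rng.normal(0.0, 1.0, n0)
            l1 = (rng.normal(cfg.mean_shift, cfg.sd_inflation, n1)
                  + rng.normal(0.0, cfg.heterogeneity_sd, n1))
            rows.append((l0, l1))
        p0 = np.corrcoef(rows[0][0], rows[1][0])[0, 1]
        p1 = np.corrcoef(rows[0][1], rows[1][1])[0, 1]
        if abs(p0) < cfg.max_abs_pcc and abs(p1) < cfg.max_abs_pcc:
            return rows, float(p0), float(p1)
    raise RuntimeError(
        f"rejection sampling failed after {_MAX_PAIR_RETRIES} tries; "
        "try a looser max_abs_pcc"
    )


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Generate the full fixture bundle, deterministic in ``cfg.rng_seed``.

    Background genes are i.i.d. standard normal per sample. The interactome
    is a Barabasi-Albert scale-free graph over all genes (uniform random
    edge confidences) with the planted pairs merged in; seeds are a random
    subset of disease genes and the answer set a random subset of planted
    pairs (both at least 1 when any pair is planted).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _gene_names(cfg.n_genes)
    n0, n1 = cfg.n_samples_class0, cfg.n_samples_class1
    sample_ids = [f"N{i:03d}" for i in range(1, n0 + 1)] + \
                 [f"D{i:03d}" for i in range(1, n1 + 1)]
    labels = np.array([0] * n0 + [1] * n1, dtype=int)

    values = rng.normal(0.0, 1.0, size=(cfg.n_genes, n0 + n1))

    disease_genes = list(rng.choice(cfg.n_genes, size=2 * cfg.n_disease_pairs,
                                    replace=False))
    truth_rows = []
    for k in range(cfg.n_disease_pairs):
        ia, ib = disease_genes[2 * k], disease_genes[2 * k + 1]
        rows, p0, p1 = _planted_pair_values(rng, cfg)
        for idx, (l0, l1) in zip((ia, ib), rows):
            values[idx, :n0] = l0
            values[idx, n0:] = l1
        a, b = canonical_pair(genes[ia], genes[ib])
        truth_rows.append({"gene_a": a, "gene_b": b,
                           "pcc_l0": p0, "pcc_l1": p1})
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_a", "gene_b", "pcc_l0", "pcc_l1"])

    ds = ExpressionDataset(gene_ids=tuple(genes), sample_ids=tuple(sample_ids),
                           values=values, labels=labels)

    ba_seed = int(rng.integers(2**31))
    graph = nx.barabasi_albert_graph(cfg.n_genes,
                                     cfg.interactome_degree_param, seed=ba_seed)
    net = Interactome()
    for i, j in sorted(graph.edges()):
        net.add_edge(genes[i], genes[j], float(rng.uniform()))
    for _, row in truth.iterrows():
        if (row["gene_a"], row["gene_b"]) not in net:
            net.add_edge(row["gene_a"], row["gene_b"], float(rng.uniform()))

    seeds: set = set()
    answer: set = set()
    if cfg.n_disease_pairs:
        n_seeds = max(1, int(round(cfg.seed_fraction * 2 * cfg.n_disease_pairs)))
        seed_idx = rng.choice(len(disease_genes), size=n_seeds, replace=False)
        seeds = {genes[disease_genes[i]] for i in seed_idx}
        n_answer = max(1, int(round(cfg.answer_fraction * cfg.n_disease_pairs)))
        ans_idx = rng.choice(cfg.n_disease_pairs, size=n_answer, replace=False)
        answer = {canonical_pair(truth.iloc[i]["gene_a"], truth.iloc[i]["gene_b"])
                  for i in ans_idx}

    return SimulatedData(dataset=ds, interactome=net, seeds=seeds,
                         answer_set=answer, truth=truth)


def write_fixtures(sim: SimulatedData, outdir) -> dict:
    """Write every fixture in the exact text formats the pipeline reads.

    Returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "interactome": outdir / "interactome.tsv",
        "seeds": outdir / "seeds.txt",
        "answer_set": outdir / "answer_set.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(sim.dataset, paths["expression"], paths["labels"])
    confs = {e: sim.interactome.confidence(e) for e in sim.interactome.edges()}
    write_edge_list(paths["interactome"], sim.interactome.edges(), confs)
    with open(paths["seeds"], "w") as fh:
        for g in sorted(sim.seeds):
            fh.write(g + "\n")
    write_edge_list(paths["answer_set"], sim.answer_set)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return {k: str(v) for k, v in paths.items()}
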