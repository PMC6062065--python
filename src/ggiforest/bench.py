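"""End-to-end planted-pair recovery benchmark.

Glue used by the test suite and the acceptance script: simulate a
benchmark, build the balanced labelled set with planted pairs as
positives, extract features, cross-validate the forest and score the
single-feature |PCC| baseline on the same pairs.
"""

from __future__ import annotations

from dataclasses import replace

from .expression import zscore_normalise
from .features import GenePair, feature_matrix
from .forest import correlation_baseline, cross_validate
from .labeling import build_labeled_set
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["run_recovery_benchmark"]


def run_recovery_benchmark(rng_seed: int, cfg: SimulationConfig = None, *,
                           bins: int = 10, folds: int = 10, t: int = 100) -> dict:
    """Run the default synthetic benchmark at one seed.

    Positives are the planted truth pairs (used directly as the answer
    set, no seed expansion, interactome edges not added); negatives are
    balanced random non-interacting pairs. Returns forest CV metrics and
    the baseline's ROC area / best thresholded accuracy.
    """
    cfg = replace(cfg or SimulationConfig(), rng_seed=rng_seed)
    sim = simulate_dataset(cfg)
    ds = zscore_normalise(sim.dataset)
    labeled = build_labeled_set(
        sim.truth_pairs, sim.interactome, seeds=None, ds=ds,
        rng_seed=rng_seed, include_net_edges=False)
    pairs = [GenePair.from_dataset(ds, a, b) for a, b in labeled.pairs]
    X, _ = feature_matrix(pairs, bins=bins, rng_seed=rng_seed)
    y = labeled.labels
    report = cross_validate(X, y, folds=folds, rng_seed=rng_seed, t=t)
    baseline = correlation_baseline(X, y)
    return {
        "n_pairs": len(y),
        "forest": report,
        "forest_accuracy": report.accuracy,
        "forest_roc_area": report.roc_area,
        "baseline_roc_area": baseline["roc_area"],
        "baseline_accuracy": baseline["accuracy"],
    }
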