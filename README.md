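# ggiforest

Random-forest identification of gene–gene interactions (GGIs) from
heterogeneous two-class gene expression profiles.

When expression values are heterogeneous across samples of the same
condition, plain correlation thresholds (PCC, MI) fail to separate
disease-relevant gene pairs from background. `ggiforest` instead encodes
each gene pair as a 22-dimensional statistical feature vector — per-class
means, sample SDs, max−min ranges, Welch t statistics between the four
list pairings, within-class Pearson correlation and mutual information,
and cross-class mutual information after order-preserving undersampling —
and trains a 100-tree random forest on pairs labelled via a curated answer
set boosted by seed-gene neighbourhood expansion over an interactome, with
balanced randomly sampled non-interacting negatives. The trained model is
then applied to interactome-restricted candidate pairs of a new dataset to
predict a GGI network, from which a top-degree hub subnetwork is
extracted.

A synthetic-data generator produces expression matrices with planted
low-correlation "disease" pairs, a scale-free interactome, seed genes and
an answer set, so the entire pipeline is testable offline.

## Library layout

| module | role |
| --- | --- |
| `ggiforest.expression` | TSV parsing/validation, per-gene z-score normalisation, per-class list extraction |
| `ggiforest.features` | the 22 pair features (`welch_t`, `pcc`, `mutual_information`, `undersample`, `compute_features`, `feature_matrix`) |
| `ggiforest.labeling` | interactome handling, confidence filtering, seed-neighbour positive expansion, balanced negative sampling |
| `ggiforest.forest` | random-forest training, vote-based prediction, stratified CV with support-weighted metrics, Gini feature importance |
| `ggiforest.network` | candidate-pair classification, predicted-network export, hub subnetwork extraction, correlation audit of novel predictions |
| `ggiforest.simulate` | synthetic fixture generator (planted pairs with capped |PCC|) |
| `ggiforest.cli` | command-line pipeline |
| `ggiforest.bench` | end-to-end planted-pair recovery benchmark |

## CLI

All commands accept `--config cfg.yaml` (flags override config keys) and
write a `.meta.json` sidecar with the resolved parameters, their hash and
the seed next to every output.

```sh
# 1. generate fixtures (or bring your own TSVs)
ggiforest simulate --out-dir fixtures --seed 7

# 2. balanced labelled pair set + 22-feature matrix
ggiforest build-training \
    --expression fixtures/expression.tsv --labels fixtures/labels.tsv \
    --interactome fixtures/interactome.tsv --answer-set fixtures/answer_set.tsv \
    --seeds fixtures/seeds.txt --out training.tsv --seed 7

# 3. train / evaluate
ggiforest train --features training.tsv --model-out model.joblib --seed 7
ggiforest evaluate --features training.tsv --out metrics.json --folds 10 --seed 7

# 4. apply to a new dataset over interactome-restricted candidates
ggiforest classify --model model.joblib \
    --expression fixtures/expression.tsv --labels fixtures/labels.tsv \
    --interactome fixtures/interactome.tsv --out predicted.tsv --seed 7

# 5. top-degree hub subnetwork
ggiforest network --edges predicted.tsv --out-prefix hub --top-k 20
```

File formats are all plain TSV/text: expression matrix (`gene_id` +
sample columns), labels (`sample_id<TAB>label`), edge lists
(`gene_a<TAB>gene_b[<TAB>confidence]`), seed lists (one gene per line).

## Acceptance

Acceptance is property-based (see `tests/test_acceptance.py`): feature
oracle equivalence against an independent brute-force implementation,
analytic limits, labeling correctness, synthetic planted-pair recovery
(forest ≥ 0.85 accuracy / ≥ 0.90 ROC area while a single-feature |PCC|
baseline stays ≤ 0.65), byte-level end-to-end determinism, hub-ranking
oracles and exact weighted-metric arithmetic.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full pipeline on the default synthetic benchmark, prints the
measured metrics to stderr and writes the (empty — there are no numeric
targets) acceptance JSON.
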