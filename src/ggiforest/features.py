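"""Pair-level feature extraction.

Every gene pair is summarised by 22 statistics computed from its four
expression lists (gene A / gene B x class 0 / class 1): per-list means,
sample standard deviations and max-min ranges, Welch t statistics between
the four list pairings, within-class Pearson correlations, within-class
mutual information, and cross-class mutual information per gene after
order-preserving undersampling of the larger class.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionDataset, extract_lists

logger = logging.getLogger(__name__)

#: fixed feature order; column order of every feature matrix.
FEATURE_NAMES = (
    "Mean_A_L0", "Mean_A_L1", "Mean_B_L0", "Mean_B_L1",
    "SD_A_L0", "SD_A_L1", "SD_B_L0", "SD_B_L1",
    "dMm_A_L0", "dMm_A_L1", "dMm_B_L0", "dMm_B_L1",
    "WT_A_L0_B_L0", "WT_A_L1_B_L1", "WT_A_L0_A_L1", "WT_B_L0_B_L1",
    "PCC_A_L0_B_L0", "PCC_A_L1_B_L1",
    "MI_A_L0_B_L0", "MI_A_L1_B_L1", "MI_A_L0_A_L1", "MI_B_L0_B_L1",
)

N_FEATURES = len(FEATURE_NAMES)

#: signed sentinel returned by `welch_t` when variances vanish but means differ.
WELCH_SENTINEL = 1e12

__all__ = [
    "FEATURE_NAMES", "N_FEATURES", "WELCH_SENTINEL",
    "GenePair", "PairFeatureVector",
    "welch_t", "pcc", "mutual_information", "undersample",
    "compute_features", "feature_matrix", "write_feature_table",
]


@dataclass(frozen=True)
class GenePair:
    """A gene pair and its four per-class expression lists.

    Pair identity is unordered; `make` canonicalises by lexicographic gene
    id. The two class-0 lists must have equal length, likewise class-1.
    """

    gene_a: str
    gene_b: str
    e_a_l0: np.ndarray
    e_a_l1: np.ndarray
    e_b_l0: np.ndarray
    e_b_l1: np.ndarray

    def __post_init__(self):
        for name in ("e_a_l0", "e_a_l1", "e_b_l0", "e_b_l1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if len(self.e_a_l0) != len(self.e_b_l0) or len(self.e_a_l1) != len(self.e_b_l1):
            raise ValueError("class list lengths differ between the two genes")

    @classmethod
    def make(cls, gene_a, gene_b, e_a_l0, e_a_l1, e_b_l0, e_b_l1) -> "GenePair":
        """Build a canonically ordered pair (gene_a < gene_b)."""
        if str(gene_b) < str(gene_a):
            gene_a, gene_b = gene_b, gene_a
            e_a_l0, e_b_l0 = e_b_l0, e_a_l0
            e_a_l1, e_b_l1 = e_b_l1, e_a_l1
        return cls(str(gene_a), str(gene_b), e_a_l0, e_a_l1, e_b_l0, e_b_l1)

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, gene_a: str, gene_b: str) -> "GenePair":
        ea0, ea1 = extract_lists(ds, gene_a)
        eb0, eb1 = extract_lists(ds, gene_b)
        return cls.make(gene_a, gene_b, ea0, ea1, eb0, eb1)

    @property
    def pair_id(self) -> str:
        a, b = sorted((self.gene_a, self.gene_b))
        return f"{a}|{b}"


@dataclass(frozen=True)
class PairFeatureVector:
    """The 22 features of one pair, in `FEATURE_NAMES` order, always finite."""

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(vals)}")
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite feature value")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))


def welch_t(x, y) -> float:
    """Welch's t statistic (x minus y), sample variances with ddof=1.

    Degenerate cases are mapped to finite values: 0 when both variance
    terms vanish and the means agree, a signed ``WELCH_SENTINEL`` when they
    vanish but the means differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 elements per list")
    d = x.mean() - y.mean()
    denom = np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y)
    if denom == 0.0:
        if d == 0.0:
            return 0.0
        logger.debug("welch_t: zero variance with unequal means, sentinel returned")
        return float(np.copysign(WELCH_SENTINEL, d))
    return float(d / np.sqrt(denom))


def pcc(x, y) -> float:
    """Pearson correlation; 0 (not NaN) if either list has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("pcc needs at least 2 elements")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _bin_indices(v: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index per element over the list's own [min, max].

    A constant list puts all mass in bin 0; the maximum maps to the top bin.
    """
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(len(v), dtype=np.intp)
    idx = np.floor((v - lo) / (hi - lo) * bins).astype(np.intp)
    return np.minimum(idx, bins - 1)


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in mutual information in bits after equal-width binning.

    Each list is discretised independently into `bins` bins over its own
    range; MI is the sum of p(i,j) log2(p(i,j)/(p(i)p(j))) over occupied
    joint cells. Always >= 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("mutual_information needs at least 2 elements")
    if bins < 1:
        raise ValueError("bins must be positive")
    bx = _bin_indices(x, bins)
    by = _bin_indices(y, bins)
    joint = np.zeros((bins, bins), dtype=float)
    np.add.at(joint, (bx, by), 1.0)
    joint /= len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ii, jj = np.nonzero(nz)
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px[ii] * py[jj]))))
    return max(mi, 0.0)


def undersample(longer, target_len: int, rng_seed: int) -> np.ndarray:
    """Keep `target_len` elements chosen uniformly without replacement,
    preserving the original relative order. Deterministic given `rng_seed`."""
    longer = np.asarray(longer, dtype=float)
    if target_len > len(longer):
        raise ValueError(f"target_len {target_len} exceeds list length {len(longer)}")
    if target_len == len(longer):
        return longer.copy()
    rng = np.random.default_rng(rng_seed)
    keep = np.sort(rng.choice(len(longer), size=target_len, replace=False))
    return longer[keep]


def _subseed(rng_seed: int, *parts) -> int:
    """Stable 64-bit stream seed from a global seed plus string parts."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(rng_seed)).encode())
    for p in parts:
        h.update(b"\x00")
        h.update(str(p).encode())
    return int.from_bytes(h.digest(), "little")


def _cross_class_mi(e_l0, e_l1, bins, seed) -> float:
    """MI between a gene's two class lists after equalising lengths by
    order-preserving undersampling of the longer list; elements then pair
    by position."""
    if len(e_l0) > len(e_l1):
        e_l0 = undersample(e_l0, len(e_l1), seed)
    elif len(e_l1) > len(e_l0):
        e_l1 = undersample(e_l1, len(e_l0), seed)
    return mutual_information(e_l0, e_l1, bins)


def compute_features(pair: GenePair, bins: int = 10, rng_seed: int = 0) -> PairFeatureVector:
    """Compute the full 22-feature vector for one pair.

    The undersampling stream for each cross-class MI feature is derived
    from ``rng_seed`` and the gene's own identifier, so results are
    reproducible and invariant under A/B slot swapping.
    """
    a0, a1, b0, b1 = pair.e_a_l0, pair.e_a_l1, pair.e_b_l0, pair.e_b_l1
    for lst in (a0, a1, b0, b1):
        if len(lst) < 2:
            raise ValueError("each expression list needs at least 2 elements")
    sd = lambda v: float(np.std(v, ddof=1))
    rng_range = lambda v: float(v.max() - v.min())
    vals = (
        float(a0.mean()), float(a1.mean()), float(b0.mean()), float(b1.mean()),
        sd(a0), sd(a1), sd(b0), sd(b1),
        rng_range(a0), rng_range(a1), rng_range(b0), rng_range(b1),
        welch_t(a0, b0), welch_t(a1, b1), welch_t(a0, a1), welch_t(b0, b1),
        pcc(a0, b0), pcc(a1, b1),
        mutual_information(a0, b0, bins), mutual_information(a1, b1, bins),
        _cross_class_mi(a0, a1, bins, _subseed(rng_seed, pair.gene_a)),
        _cross_class_mi(b0, b1, bins, _subseed(rng_seed, pair.gene_b)),
    )
    return PairFeatureVector(vals)


def feature_matrix(pairs, bins: int = 10, rng_seed: int = 0):
    """Feature vectors for a list of pairs.

    Returns ``(X, pair_ids)`` where ``X`` is (n_pairs x 22) in
    `FEATURE_NAMES` column order. Row values depend only on the pair and
    ``rng_seed``, never on position in the input list.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    X = np.empty((len(pairs), N_FEATURES), dtype=float)
    ids = []
    for i, p in enumerate(pairs):
        X[i] = compute_features(p, bins=bins, rng_seed=rng_seed).values
        ids.append(p.pair_id)
    return X, ids


def write_feature_table(path, X, pairs, labels=None) -> None:
    """TSV export: pair_id, gene_a, gene_b, the 22 features, optional label."""
    import pandas as pd

    pairs = list(pairs)
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(FEATURE_NAMES))
    df.insert(0, "pair_id", [p.pair_id for p in pairs])
    df.insert(1, "gene_a", [min(p.gene_a, p.gene_b) for p in pairs])
    df.insert(2, "gene_b", [max(p.gene_a, p.gene_b) for p in pairs])
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
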