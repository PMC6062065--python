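"""Two-class expression matrices: parsing, validation and z-score normalisation.

The on-disk dialect is plain TSV: the matrix has a ``gene_id`` header column
followed by one column per sample; the label file maps every sample id to a
class in ``{0, 1}`` (0 = normal, 1 = disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "zscore_normalise",
    "extract_lists",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples matrix with a binary class label per sample.

    Attributes
    ----------
    gene_ids : tuple of str
        Row identifiers, unique, in matrix order.
    sample_ids : tuple of str
        Column identifiers, unique, in matrix order.
    values : ndarray of shape (n_genes, n_samples)
        Expression values (unitless after normalisation).
    labels : ndarray of shape (n_samples,)
        Per-sample class in {0, 1}; both classes must be non-empty.
    normalised : bool
        Whether rows have been z-scored.
    zero_variance_genes : tuple of str
        Genes whose original row variance was zero (flagged during
        normalisation; their rows are all-zero afterwards).
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray
    labels: np.ndarray
    normalised: bool = False
    zero_variance_genes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label required per sample")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be in {{0, 1}}, got {sorted(bad)}")
        for cls in (0, 1):
            if not np.any(self.labels == cls):
                raise ValueError(f"class {cls} has no samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_sizes(self) -> tuple:
        """(n class-0 samples, n class-1 samples)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None


def read_expression(matrix_path, labels_path) -> "ExpressionDataset":
    """Parse a TSV expression matrix plus a sample-label file.

    Duplicate gene rows are collapsed by element-wise mean (logged).
    Raises ``ValueError`` on a non-numeric cell (naming gene and sample),
    on a sample missing from the label file, and when all samples share
    one class.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, comment="#")
    sample_ids = [str(c) for c in raw.columns]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        gi, si = np.argwhere(mask.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value for gene {raw.index[gi]!r}, "
            f"sample {sample_ids[si]!r}"
        )
    if numeric.index.duplicated().any():
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene id(s) by mean: %s", len(dups), dups
        )
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]

    lab = pd.read_csv(labels_path, sep="\t", header=None, dtype=str, comment="#")
    if lab.shape[1] != 2:
        raise ValueError("label file must have exactly 2 columns")
    if list(lab.iloc[0]) == ["sample_id", "label"]:
        lab = lab.iloc[1:]
    label_map = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    labels = []
    for s in sample_ids:
        if s not in label_map:
            raise ValueError(f"sample {s!r} has no label")
        val = label_map[s]
        if val not in ("0", "1"):
            raise ValueError(f"label for sample {s!r} must be 0 or 1, got {val!r}")
        labels.append(int(val))
    return ExpressionDataset(
        gene_ids=tuple(str(g) for g in numeric.index),
        sample_ids=tuple(sample_ids),
        values=numeric.to_numpy(dtype=float),
        labels=np.array(labels, dtype=int),
    )


def write_expression(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write the matrix and labels in the exact dialect `read_expression` reads."""
    df = pd.DataFrame(ds.values, index=list(ds.gene_ids), columns=list(ds.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    with open(labels_path, "w") as fh:
        for s, l in zip(ds.sample_ids, ds.labels):
            fh.write(f"{s}\t{int(l)}\n")


def zscore_normalise(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each gene row across all samples pooled (both classes).

    Uses the sample standard deviation (ddof=1). Zero-variance rows become
    all-zero and are recorded in ``zero_variance_genes``.
    """
    if ds.normalised:
        raise ValueError("dataset is already normalised")
    vals = ds.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True) if vals.shape[1] > 1 else np.zeros_like(mean)
    # relative tolerance: a numerically constant row has sd at rounding level
    scale = np.maximum(np.abs(vals).max(axis=1), 1e-300)
    flat = sd[:, 0] <= 1e-12 * scale
    out = np.zeros_like(vals)
    ok = ~flat
    out[ok] = (vals[ok] - mean[ok]) / sd[ok]
    zero_var = tuple(g for g, f in zip(ds.gene_ids, flat) if f)
    if zero_var:
        logger.warning("%d zero-variance gene row(s) set to 0: %s",
                       len(zero_var), list(zero_var[:10]))
    return replace(ds, values=out, normalised=True, zero_variance_genes=zero_var)


def extract_lists(ds: ExpressionDataset, gene: str):
    """Split one gene's row into its class-0 and class-1 expression lists.

    Returns ``(E_L0, E_L1)`` in sample order; raises ``KeyError`` for an
    unknown gene.
    """
    row = ds.values[ds.gene_index(gene)]
    return row[ds.labels == 0].copy(), row[ds.labels == 1].copy()
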