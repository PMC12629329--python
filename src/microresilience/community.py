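"""Compositional transforms, alpha-diversity, Aitchison distance, ordination.

Genus count data are compositional: only relative information is
meaningful.  The centred log-ratio (CLR) transform,
``clr(x)_j = ln x_j − mean_k ln x_k``, maps a (pseudocounted) composition
into ordinary Euclidean geometry, where the Euclidean distance between two
CLR vectors is the Aitchison distance.  Diversity metrics, by contrast,
operate on the raw unfiltered counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import GenusCountTable, ValidationError

logger = logging.getLogger("microresilience")

__all__ = [
    "CLRMatrix",
    "OrdinationResult",
    "clr_transform",
    "observed_richness",
    "shannon_diversity",
    "alpha_diversity",
    "aitchison_distance",
    "prevalence_filter",
    "pca_ordination",
    "log2_abundance",
]


@dataclass
class CLRMatrix:
    """CLR-transformed abundances; rows sum to zero by construction."""

    values: pd.DataFrame  # samples × taxa, real-valued

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values.loc[sample_id].to_numpy(dtype=float)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples × components
    explained_variance_fraction: np.ndarray


def clr_transform(table: GenusCountTable, pseudocount: float = 1.0) -> CLRMatrix:
    """Centred log-ratio transform of pseudocounted counts.

    value[i, j] = ln(c[i, j] + p) − mean_j ln(c[i, j] + p); every row sums
    to zero (within floating-point error).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CLRMatrix(
        pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)
    )


def observed_richness(counts_row: np.ndarray | pd.Series) -> int:
    """Number of genera with a strictly positive count."""
    arr = np.asarray(counts_row)
    return int((arr > 0).sum())


def shannon_diversity(
    counts_row: np.ndarray | pd.Series, log_base: float = np.e
) -> float:
    """Shannon index H = −Σ p_j log(p_j) over detected genera."""
    arr = np.asarray(counts_row, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValidationError("Shannon diversity undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def alpha_diversity(table: GenusCountTable, log_base: float = np.e) -> pd.DataFrame:
    """Per-sample observed richness and Shannon diversity (unfiltered counts)."""
    rows = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        rows.append(
            dict(
                sample_id=sid,
                richness=observed_richness(row),
                shannon=shannon_diversity(row, log_base=log_base),
            )
        )
    return pd.DataFrame(rows)


def aitchison_distance(
    row_a: np.ndarray | pd.Series, row_b: np.ndarray | pd.Series
) -> float:
    """Euclidean distance between two CLR vectors.

    Inputs must share taxon ordering; labelled inputs (Series) are checked
    for index agreement.
    """
    if isinstance(row_a, pd.Series) and isinstance(row_b, pd.Series):
        if not row_a.index.equals(row_b.index):
            raise ValidationError("mismatched taxon sets in distance computation")
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("CLR vectors differ in length")
    return float(np.linalg.norm(a - b))


def prevalence_filter(
    table: GenusCountTable, threshold: float = 0.15
) -> GenusCountTable:
    """Drop genera detected in fewer than ``threshold`` of all samples.

    A genus is retained when present (count > 0) in at least the given
    fraction of samples (boundary inclusive).  Pure column selection:
    retained counts and the sample set are unchanged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence[prevalence >= threshold].index
    removed = table.n_taxa - len(keep)
    logger.info(
        "prevalence_filter: removed %d of %d taxa below prevalence %.0f%%",
        removed,
        table.n_taxa,
        100 * threshold,
    )
    if len(keep) == 0:
        logger.warning("prevalence_filter: no taxa retained")
    return GenusCountTable(table.counts[list(keep)].copy(), dict(table.meta))


def pca_ordination(clr: CLRMatrix, n_components: int = 2) -> OrdinationResult:
    """PCA of the column-centred CLR matrix (no unit-variance scaling)."""
    n_samples = len(clr.sample_ids)
    if n_samples < 2:
        raise ValueError("ordination requires at least 2 samples")
    if n_components > n_samples:
        raise ValueError(
            f"requested {n_components} components from {n_samples} samples"
        )
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):
        scores = pca.fit_transform(clr.values.to_numpy(dtype=float))
        ratio = pca.explained_variance_ratio_
    # identical samples: zero total variance, define all fractions as 0
    ratio = np.nan_to_num(ratio, nan=0.0)
    return OrdinationResult(
        sample_ids=clr.sample_ids,
        scores=scores,
        explained_variance_fraction=ratio,
    )


def log2_abundance(table: GenusCountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(count + pseudocount), used for abundance display."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(table.counts.astype(float) + pseudocount)
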