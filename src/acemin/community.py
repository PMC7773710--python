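"""Community-succession metrics on ASV count tables.

Operates on amplicon sequence variant (ASV) × sample count matrices as
produced by a standard 16S denoising pipeline, held as pandas DataFrames
with ASV ids on the index and sample ids on the columns.  Provides the
descriptive pathway used to characterize the oxic → sulfidogenic community
shift: relative abundances, rank-level aggregation with an "Others" bucket,
rarefaction to a common depth, Bray–Curtis dissimilarity, principal
coordinates analysis (classical metric scaling), and a silhouette-based
check that phase labels form separated clusters in the ordination.

Aggregation follows the stacked-bar convention: a taxon is kept on its own
if it reaches the threshold in at least one sample (max-over-samples rule),
otherwise it is summed into "Others".  Rarefaction is a single multivariate
hypergeometric draw per sample (subsampling without replacement), seeded
for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "relative_abundance",
    "aggregate_taxa",
    "rarefy",
    "bray_curtis",
    "pcoa",
    "cluster_separation",
    "TAXONOMY_RANKS",
]

TAXONOMY_RANKS = ("class", "order", "genus")
OTHERS_LABEL = "Others"


@dataclass
class DissimilarityMatrix:
    """Square symmetric Bray–Curtis matrix with sample labels."""

    data: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.ndim != 2 or self.data.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if len(self.ids) != n:
            raise ValueError("number of ids must match matrix size")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(self.data < -1e-12) or np.any(self.data > 1 + 1e-12):
            raise ValueError("Bray-Curtis values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``eigenvalues`` holds every eigenvalue of the centered Gower matrix in
    decreasing order with negative values clamped to zero; coordinates are
    returned only for strictly positive eigenvalues.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _check_counts(table: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    return table


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance profiles (columns sum to 1)."""
    table = _check_counts(table)
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    return table.div(totals, axis=1)


def aggregate_taxa(
    profiles: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str,
    threshold: float,
) -> pd.DataFrame:
    """Sum ASV profiles by taxon at ``rank``; bucket rare taxa into "Others".

    A taxon stays on its own iff its relative abundance reaches ``threshold``
    in at least one sample.  ``threshold = 0`` disables the bucket.  Column
    totals are conserved exactly.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMY_RANKS}")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold!r}")
    labels = taxonomy[rank].reindex(profiles.index).fillna("unassigned")
    grouped = profiles.groupby(labels.to_numpy()).sum()
    if threshold == 0:
        return grouped
    retained_mask = grouped.max(axis=1) >= threshold
    retained = grouped[retained_mask]
    # most-abundant first, Others always last
    retained = retained.loc[retained.mean(axis=1).sort_values(ascending=False).index]
    rare = grouped[~retained_mask]
    if len(rare):
        others = rare.sum(axis=0).to_frame(OTHERS_LABEL).T
        retained = pd.concat([retained, others])
    return retained


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample column to ``depth`` reads without replacement.

    One multivariate hypergeometric draw per sample; reproducible under the
    same seed.  ``depth`` may not exceed any sample's total count.
    """
    table = _check_counts(table)
    counts = table.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = counts.astype(np.int64)
    totals = counts.sum(axis=0)
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    short = [c for c, tot in zip(table.columns, totals) if tot < depth]
    if short:
        raise ValueError(f"depth {depth} exceeds the total count of sample(s) {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between samples.

    Accepts counts or relative-abundance profiles (samples on columns).
    """
    table = _check_counts(table)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    matrix = squareform(pdist(table.to_numpy(dtype=float).T, metric="braycurtis"))
    return DissimilarityMatrix(matrix, list(table.columns))


def pcoa(dm, ids: Sequence | None = None) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers −½·D² and eigendecomposes; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues.  Negative
    eigenvalues — non-Euclidean input — are clamped to zero, reported, and
    excluded from the coordinates; no Lingoes/Cailliez correction is applied.
    """
    if isinstance(dm, DissimilarityMatrix):
        d = dm.data
        labels = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        labels = list(ids) if ids is not None else list(range(d.shape[0]))
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")

    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ (d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    clamped = np.where(eigvals > 0, eigvals, 0.0)
    total = clamped.sum()
    proportion = clamped / total if total > 0 else clamped
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=clamped,
        proportion_explained=proportion,
    )


def cluster_separation(dm, labels: Sequence) -> float:
    """Mean silhouette of the given sample grouping on a dissimilarity matrix.

    Values near 1 indicate well-separated groups (e.g., phase-1 vs phase-2
    communities); values near 0 indicate no structure.
    """
    d = dm.data if isinstance(dm, DissimilarityMatrix) else np.asarray(dm, dtype=float)
    labels = np.asarray(list(labels))
    if len(labels) != d.shape[0]:
        raise ValueError("need one label per sample")
    unique, counts = np.unique(labels, return_counts=True)
    if len(unique) < 2:
        raise ValueError(f"need at least 2 label groups, got {len(unique)}")
    if np.any(counts == 0):
        raise ValueError("every label group must be non-empty")
    return float(silhouette_score(d, labels, metric="precomputed"))
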