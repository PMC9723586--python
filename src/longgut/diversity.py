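"""Phylogenetic alpha diversity, community distances, and ordination.

Faith's PD and weighted UniFrac are computed through scikit-bio; the PD
convention includes the path to the root, and the weighted UniFrac
``normalized`` variant bounds distances in [0, 1] by dividing by the maximal
attainable branch-weighted separation. PCoA is the classical Gower
double-centering eigendecomposition; negative eigenvalues are reported, not
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.distance import DistanceMatrix
from scipy.spatial.distance import pdist, squareform

from .core import CountTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "faith_pd",
    "faith_pd_table",
    "weighted_unifrac",
    "bray_curtis",
    "pcoa",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x positive-eigenvalue axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over positive eigenvalues

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


def _check_taxa_in_tree(taxon_ids, tree: TreeNode, present=None) -> None:
    tips = {t.name for t in tree.tips()}
    taxa = np.asarray(taxon_ids)
    if present is not None:
        taxa = taxa[np.asarray(present)]
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")


def faith_pd(sample_row: np.ndarray, taxon_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sum of branch lengths of the minimal subtree connecting the taxa present
    in the sample and the root. Zero when no taxon is present.
    """
    row = np.asarray(sample_row, dtype=float)
    if not (row > 0).any():
        return 0.0
    _check_taxa_in_tree(taxon_ids, tree, present=row > 0)
    return float(_skbio_faith_pd(row, taxa=list(taxon_ids), tree=tree))


def faith_pd_table(table: CountTable, tree: TreeNode) -> pd.Series:
    """Faith's PD for every sample of a count table."""
    values = [faith_pd(table.counts[i], table.taxon_ids, tree) for i in range(table.n_samples)]
    return pd.Series(values, index=list(table.sample_ids), name="faith_pd")


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    Each branch contributes its length times the absolute difference in the
    proportion of each sample's reads descending from it.
    """
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"empty samples have no defined UniFrac distance: {bad}")
    _check_taxa_in_tree(table.taxon_ids, tree)
    return beta_diversity(
        "weighted_unifrac",
        table.counts,
        ids=list(table.sample_ids),
        taxa=list(table.taxon_ids),
        tree=tree,
        normalized=normalized,
        validate=True,
    )


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: ``1 - 2 * sum(min(x, y)) / (sum x + sum y)``."""
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {bad}")
    condensed = pdist(table.counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis.

    Double-centers ``-D**2 / 2`` (Gower), eigendecomposes, and returns
    coordinates ``eigvec * sqrt(eigval)`` for strictly positive eigenvalues.
    Proportions of variance are taken over the positive part of the spectrum;
    negative eigenvalues (non-Euclidean input) are surfaced in
    ``eigenvalues`` so callers can judge embedding quality.
    """
    d = dist.data
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    explained = eigval[pos] / eigval[pos].sum() if pos.any() else np.empty(0)
    return OrdinationResult(
        sample_ids=tuple(dist.ids),
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=explained,
    )


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """Serialize as a square TSV with a leading id header row and column."""
    dist.to_data_frame().to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=[str(i) for i in frame.index])
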