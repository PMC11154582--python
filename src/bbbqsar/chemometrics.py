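"""Descriptor intercorrelation: correlation-matrix PCA and variable clustering.

QSAR predictors must not be intercorrelated, so before any model is built the
candidate descriptors (MW, polarizability, TPSA, HBD+HBA, NRB) are examined
with principal component analysis of their correlation matrix and with
agglomerative clustering of a correlation-based similarity.  The analysis
yields the non-redundant predictor blocks: a size block {MW, alpha}, a
polarity block {TPSA, HB_total} and the flexibility descriptor NRB on its
own.

Similarity between two variables with Pearson correlation r is expressed as a
percentage.  Two conventions are implemented:

* ``"correlation-distance"`` (default): 100 * (1 + r) / 2, the similarity
  scale of dendrograms built on the correlation distance d = 1 - r with
  maximum distance 2.  Calibrated against the published pairwise values
  (MW vs alpha = 92.57%).
* ``"absolute-correlation"``: 100 * |r|.

The default linkage is single linkage, which on the study panel reproduces
the published dendrogram merge levels; average and complete linkage are
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PcaResult",
    "VariableClustering",
    "DegenerateColumnError",
    "standardize",
    "run_pca",
    "variable_similarity",
    "similarity_matrix",
    "cluster_variables",
    "SIMILARITY_CONVENTIONS",
    "DEFAULT_CONVENTION",
    "DEFAULT_LINKAGE",
]

SIMILARITY_CONVENTIONS = ("correlation-distance", "absolute-correlation")
DEFAULT_CONVENTION = "correlation-distance"
DEFAULT_LINKAGE = "single"


class DegenerateColumnError(ValueError):
    """A descriptor column has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA of a descriptor panel.

    ``loadings`` columns are unit-norm eigenvectors of the correlation matrix,
    ordered by decreasing ``eigenvalues``; ``scores`` are the standardized
    data projected onto them.  Each component is oriented so its
    largest-magnitude loading is positive (a deterministic sign convention;
    published loadings may appear globally flipped per component).
    """

    loadings: pd.DataFrame          # descriptors x components
    eigenvalues: np.ndarray
    scores: pd.DataFrame            # compounds x components
    descriptor_names: tuple[str, ...]


@dataclass(frozen=True)
class VariableClustering:
    """Agglomerative clustering of variables on a percent-similarity scale."""

    similarity_matrix: pd.DataFrame
    merge_sequence: list[tuple[frozenset, frozenset, float]]
    convention_used: str
    linkage_used: str

    def cut(self, n_clusters: int) -> list[frozenset]:
        """Cluster membership after stopping at ``n_clusters`` clusters."""
        names = list(self.similarity_matrix.index)
        clusters = [frozenset([n]) for n in names]
        for a, b, _ in self.merge_sequence:
            if len(clusters) <= n_clusters:
                break
            clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        return sorted(clusters, key=lambda c: sorted(c))

    def cluster_similarity(self, members_a: Sequence[str], members_b: Sequence[str]) -> float:
        """Between-cluster similarity under the clustering's linkage rule."""
        sub = self.similarity_matrix.loc[list(members_a), list(members_b)].to_numpy()
        if self.linkage_used == "single":
            return float(sub.max())
        if self.linkage_used == "complete":
            return float(sub.min())
        return float(sub.mean())


def standardize(panel: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sample SD 1 with n-1 denominator)."""
    if len(panel) < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = panel.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise DegenerateColumnError(
            f"constant column(s) cannot be standardized: {constant}"
        )
    return (panel - panel.mean()) / sd


def run_pca(panel: pd.DataFrame) -> PcaResult:
    """Eigen-decomposition of the correlation matrix of a descriptor panel.

    The input may be raw (it is standardized internally).  Eigenvalues sum to
    the number of descriptors; scores are uncorrelated across components.
    """
    if len(panel) < panel.shape[1]:
        raise ValueError(
            f"need at least as many rows ({len(panel)}) as descriptors "
            f"({panel.shape[1]})"
        )
    z = standardize(panel)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]
    # orient: largest-|loading| entry of each component positive
    for j in range(vectors.shape[1]):
        pivot = np.argmax(np.abs(vectors[:, j]))
        if vectors[pivot, j] < 0:
            vectors[:, j] = -vectors[:, j]
    names = tuple(panel.columns)
    comp_names = [f"PC{j + 1}" for j in range(len(names))]
    loadings = pd.DataFrame(vectors, index=names, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ vectors, index=panel.index, columns=comp_names)
    return PcaResult(
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        descriptor_names=names,
    )


def variable_similarity(x, y, convention: str = DEFAULT_CONVENTION) -> float:
    """Percent similarity between two variables from their Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateColumnError("similarity is undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return _similarity_from_r(r, convention)


def _similarity_from_r(r: float, convention: str) -> float:
    if convention == "correlation-distance":
        return 100.0 * (1.0 + r) / 2.0
    if convention == "absolute-correlation":
        return 100.0 * abs(r)
    raise ValueError(
        f"unknown convention {convention!r}; choose from {SIMILARITY_CONVENTIONS}"
    )


def similarity_matrix(panel: pd.DataFrame, convention: str = DEFAULT_CONVENTION) -> pd.DataFrame:
    """Pairwise percent-similarity matrix of the panel's columns."""
    z = standardize(panel)  # raises on constant columns
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    sim = np.vectorize(lambda r: _similarity_from_r(float(r), convention))(corr)
    np.fill_diagonal(sim, 100.0)
    return pd.DataFrame(sim, index=panel.columns, columns=panel.columns)


def cluster_variables(
    similarity: pd.DataFrame,
    linkage: str = DEFAULT_LINKAGE,
    *,
    convention: str = DEFAULT_CONVENTION,
) -> VariableClustering:
    """Agglomerative clustering of variables from a percent-similarity matrix.

    Internally runs scipy hierarchical clustering on the dissimilarity
    ``100 - similarity``; merge levels are reported back on the similarity
    scale and are non-increasing along the merge sequence.
    """
    values = similarity.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(values), 100.0):
        raise ValueError("self-similarity must equal 100")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    names = list(similarity.index)
    distance = 100.0 - values
    np.fill_diagonal(distance, 0.0)
    condensed = squareform(distance, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)

    clusters: dict[int, frozenset] = {i: frozenset([n]) for i, n in enumerate(names)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = len(names)
    for a_idx, b_idx, height, _ in tree:
        a, b = clusters[int(a_idx)], clusters[int(b_idx)]
        merges.append((a, b, 100.0 - float(height)))
        clusters[next_id] = a | b
        next_id += 1
    return VariableClustering(
        similarity_matrix=similarity.copy(),
        merge_sequence=merges,
        convention_used=convention,
        linkage_used=linkage,
    )
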