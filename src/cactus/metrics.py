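"""Confidence and agreement metrics for assignment outputs.

Confidence of a cell's clone assignment is measured by the concentration of
its posterior probability vector: normalized entropy (Shannon entropy over
its maximum ``log K``) and a normalized Gini impurity, both 0 for a point
mass and 1 for the uniform distribution.  Agreement between partitions uses
the adjusted Rand index; separation of groups in an expression embedding
uses the Dunn, RMSSTD, Calinski-Harabasz and connectivity validity indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score
from sklearn.neighbors import NearestNeighbors


def _check_prob(prob: np.ndarray) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 1:
        raise ValueError("expected a 1-D probability vector")
    if (prob < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(prob.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1, got {prob.sum()}")
    return prob


def normalized_entropy(prob: np.ndarray) -> float:
    """Shannon entropy divided by its maximum log K; 0 for K = 1."""
    prob = _check_prob(prob)
    k = prob.size
    if k == 1:
        return 0.0
    nz = prob[prob > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(k))


def gini_index(prob: np.ndarray, normalized: bool = True) -> float:
    """Gini impurity ``1 - sum p^2``, by default rescaled by K/(K-1) so the
    uniform distribution scores 1 regardless of K."""
    prob = _check_prob(prob)
    k = prob.size
    if k < 2:
        raise ValueError("Gini index needs at least 2 categories")
    raw = 1.0 - float((prob**2).sum())
    return raw * k / (k - 1) if normalized else raw


@dataclass
class ConfidenceReport:
    """Per-cell and mean concentration measures for one cell subset."""

    subset: str  # "multiplet" | "singleton" | "all"
    per_cell_entropy: np.ndarray
    per_cell_gini: np.ndarray

    @property
    def mean_normalized_entropy(self) -> float:
        return float(self.per_cell_entropy.mean())

    @property
    def mean_gini(self) -> float:
        return float(self.per_cell_gini.mean())


def confidence_report(
    cell_clone_prob: np.ndarray, subset_mask: np.ndarray | None = None, subset: str = "all"
) -> ConfidenceReport:
    """Mean normalized entropy and Gini of cell-to-clone posteriors.

    ``subset_mask`` selects cells (e.g. cells in multiplet input clusters, to
    stratify confidence the way assignment tables usually are).
    """
    prob = np.asarray(cell_clone_prob, dtype=float)
    if subset_mask is not None:
        prob = prob[np.asarray(subset_mask, dtype=bool)]
    if prob.shape[0] == 0:
        raise ValueError("empty cell subset")
    ent = np.array([normalized_entropy(row) for row in prob])
    gin = np.array([gini_index(row) for row in prob])
    return ConfidenceReport(subset=subset, per_cell_entropy=ent, per_cell_gini=gin)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie chance-corrected Rand index between two partitions."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def pielou_evenness(cluster_sizes) -> float:
    """Shannon evenness of a cluster-size distribution (1 = all equal)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if sizes.size < 2:
        raise ValueError("evenness needs at least 2 clusters")
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    p = sizes / sizes.sum()
    return float(-(p * np.log(p)).sum() / np.log(sizes.size))


def cluster_validity(
    embedding: np.ndarray, labels, k_nn: int = 10
) -> dict[str, float]:
    """Internal validity indices of a grouping on an embedding.

    Returns Dunn (min between-group distance over max within-group diameter,
    higher better), RMSSTD (pooled within-group standard deviation, lower
    better), CH (Calinski-Harabasz variance ratio, higher better) and k-NN
    connectivity (penalty for neighbors split across groups, lower better).
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("embedding must be (n_cells, n_dims) matching labels")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 non-empty groups")
    if (np.bincount(np.searchsorted(uniq, labels)) == 1).any():
        warnings.warn("singleton group contributes zero diameter", stacklevel=2)

    D = squareform(pdist(X))
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, True)
    inter = D[~same]
    intra_max = 0.0
    for g in uniq:
        pts = D[np.ix_(labels == g, labels == g)]
        if pts.size > 1:
            intra_max = max(intra_max, float(pts.max()))
    dunn = float(inter.min() / intra_max) if intra_max > 0 else np.inf

    # pooled within-group variance across dimensions
    n, d = X.shape
    ss_within = 0.0
    for g in uniq:
        grp = X[labels == g]
        ss_within += float(((grp - grp.mean(axis=0)) ** 2).sum())
    rmsstd = float(np.sqrt(ss_within / (d * (n - uniq.size))))

    ch = float(calinski_harabasz_score(X, labels))

    k_nn = min(k_nn, n - 1)
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    _, idx = nn.kneighbors(X)
    conn = 0.0
    for j in range(n):
        for rank, neighbor in enumerate(idx[j, 1:], start=1):
            if labels[neighbor] != labels[j]:
                conn += 1.0 / rank
    return {"dunn": dunn, "rmsstd": rmsstd, "ch": ch, "connectivity": conn}
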