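"""Cell-to-cluster switch probabilities from BCR-derived distances.

The prior probability for cell ``j`` to be (re)assigned to cluster ``q`` is a
softmax of the negative distance, ``p[j, q] = exp(-c G[j, q]) / sum_q' ...``,
where ``G[j, q]`` counts the BCR mutations differing between the cell and the
cluster's representative sequence and ``c >= 0`` sets the prior strength
(default 2).  Cells without a sequenced BCR form their own singleton cluster;
their distance to it is 0 and to every other cluster the mean of all known
cell-to-cluster distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import DistanceMatrix, InputClustering


@dataclass
class SwitchProbabilities:
    """Row-stochastic matrix of cluster switch probabilities (cells x clusters)."""

    p: np.ndarray
    c_used: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("switch probability rows must sum to 1")

    @property
    def log_p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.p)


def bcr_distances(
    cell_bcr: dict[str, object],
    cluster_rep: dict[str, object],
    clustering: InputClustering,
) -> DistanceMatrix:
    """Distance of each cell's BCR to every cluster's representative.

    Each value in ``cell_bcr`` / ``cluster_rep`` is either a set of mutation
    identifiers (distance = size of the symmetric difference) or an aligned
    sequence string (distance = Hamming).  Cells absent from ``cell_bcr`` get
    a row of NaN to be filled by :func:`impute_missing`.
    """
    m, q = clustering.n_cells, clustering.n_clusters
    G = np.full((m, q), np.nan)
    reps = [cluster_rep[cid] for cid in clustering.cluster_ids]
    for j, cell in enumerate(clustering.cell_ids):
        if cell not in cell_bcr:
            continue
        bcr = cell_bcr[cell]
        for qi, rep in enumerate(reps):
            G[j, qi] = _distance(bcr, rep)
        own = clustering.cluster_index[j]
        if G[j, own] != 0:
            raise ValueError(
                f"cell {cell} has nonzero distance {G[j, own]} to its own cluster"
            )
    return _raw(G)


def _raw(G: np.ndarray) -> DistanceMatrix:
    # bypass finite-ness validation: NaN rows mark cells pending imputation
    dm = DistanceMatrix.__new__(DistanceMatrix)
    dm.G = G
    return dm


def _distance(a: object, b: object) -> float:
    if isinstance(a, str) and isinstance(b, str):
        if len(a) != len(b):
            raise ValueError(
                f"sequence mode requires equal lengths, got {len(a)} and {len(b)}"
            )
        return sum(x != y for x, y in zip(a, b))
    if isinstance(a, (set, frozenset)) and isinstance(b, (set, frozenset)):
        return len(a ^ b)
    raise TypeError("BCR entries must both be sequences or both mutation sets")


def impute_missing(
    dist: DistanceMatrix,
    clustering: InputClustering,
    no_bcr_cells: set[str] | None = None,
) -> DistanceMatrix:
    """Fill distances for cells without a BCR sequence.

    Such a cell keeps distance 0 to its own (singleton) cluster; every other
    entry is set to the mean of all known cell-to-cluster distances.
    """
    G = np.array(dist.G, dtype=float)
    if no_bcr_cells is None:
        missing_rows = np.flatnonzero(np.isnan(G).any(axis=1))
    else:
        missing_rows = np.array(
            [j for j, c in enumerate(clustering.cell_ids) if c in no_bcr_cells],
            dtype=int,
        )
    if missing_rows.size == 0:
        return DistanceMatrix(G)
    known = np.ones(G.shape[0], dtype=bool)
    known[missing_rows] = False
    known_values = G[known]
    if known_values.size == 0 or np.isnan(known_values).all():
        raise ValueError("no known distances to impute from")
    mean_known = float(np.nanmean(known_values))
    for j in missing_rows:
        G[j, :] = mean_known
        G[j, clustering.cluster_index[j]] = 0.0
    return DistanceMatrix(G)


def switch_probabilities(dist: DistanceMatrix, c: float = 2.0) -> SwitchProbabilities:
    """Row-wise softmax of ``-c * G``, evaluated stably in log space."""
    if c < 0:
        raise ValueError("prior strength c must be >= 0")
    G = np.asarray(dist.G, dtype=float)
    if not np.isfinite(G).all():
        raise ValueError("distances must be finite; run impute_missing first")
    logits = -c * G
    log_p = logits - logsumexp(logits, axis=1, keepdims=True)
    return SwitchProbabilities(p=np.exp(log_p), c_used=float(c))


def uniform_switch_probabilities(m: int, q: int) -> SwitchProbabilities:
    """Uninformative prior: every cell equally likely in every cluster."""
    return SwitchProbabilities(p=np.full((m, q), 1.0 / q), c_used=0.0)
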