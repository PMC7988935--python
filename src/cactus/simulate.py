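"""Synthetic data with the statistical structure the model assumes.

The generator emulates the assumed data-generating process end to end:
clone genotypes on a random perfect-phylogeny tree with the first clone as
the all-zero base clone, genotype errors at rate ``xi_true``, sparse UMI
counts with binomial allele sampling (``theta0`` in non-carrying cells,
per-position ``theta_i`` in carrying cells), a singleton-dominated cluster
size distribution, a misclustered fraction of cells, and a BCR-style
distance matrix in which misclustered cells remain close to their true
cluster.  :func:`enumerate_posterior` provides exact marginals on tiny
instances by summing the joint over all hidden states with theta and xi
clamped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .cluster_prior import SwitchProbabilities
from .data_model import (
    AlleleCounts,
    ClonalData,
    CloneGenotypes,
    DistanceMatrix,
    InputClustering,
)
from .gibbs import cell_clone_loglik


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults are the conditions of the headline recovery experiment: 4
    clones, 80 mutations, 400 cells, 15% coverage at mean depth 2, genotype
    error 5%, 5% of cells misclustered, and half the cells in multiplet
    clusters (with ``n_multiplet_clusters`` multiplet clusters; every
    remaining cell is its own singleton cluster, mirroring the
    singleton-dominated clonotype size distributions seen in BCR data).
    """

    K: int = 4
    N: int = 80
    M: int = 400
    n_multiplet_clusters: int = 50
    multiplet_fraction: float = 0.5
    explicit_sizes: list[int] | None = None
    power_law_exponent: float = 2.0
    coverage_rate: float = 0.15
    depth_mean: float = 2.0
    theta0_true: float = 0.01
    theta_dist: tuple[float, float] = (2.25, 2.65)
    theta_true: np.ndarray | None = None
    xi_true: float = 0.05
    misclustered_fraction: float = 0.05
    bcr_distance_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coverage_rate", "theta0_true", "xi_true",
                     "misclustered_fraction", "multiplet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.explicit_sizes is not None and sum(self.explicit_sizes) != self.M:
            raise ValueError("explicit cluster sizes must sum to M")


@dataclass
class GroundTruth:
    """Latent values the generator used, for recovery scoring."""

    C_true: np.ndarray  # (N, K)
    clone_of_cluster: np.ndarray  # (Q,)
    cluster_of_cell: np.ndarray  # (M,) true membership
    clone_of_cell: np.ndarray  # (M,)
    theta_true: np.ndarray
    theta0_true: float
    xi_true: float


def simulate_genotypes(
    K: int, N: int, rng: np.random.Generator, xi_true: float = 0.0
) -> tuple[np.ndarray, CloneGenotypes]:
    """Random nested clone genotypes and their error-corrupted observed copy.

    Clones sit on a random tree rooted at the all-zero base clone; each
    non-base clone owns at least one private mutation and inherits those of
    its ancestors; remaining mutations are assigned to random branches.
    The observed matrix flips each entry independently with ``xi_true``.
    """
    if K < 2:
        raise ValueError("need at least 2 clones")
    if N < K - 1:
        raise ValueError(
            f"need N >= K-1 mutations to give each non-base clone a private "
            f"mutation, got N={N}, K={K}"
        )
    parent = np.zeros(K, dtype=int)
    for k in range(1, K):
        parent[k] = rng.integers(0, k)
    # branch (owning clone) per mutation: one private each, rest random
    branch = np.empty(N, dtype=int)
    branch[: K - 1] = np.arange(1, K)
    branch[K - 1:] = rng.integers(1, K, size=N - (K - 1))
    branch = rng.permutation(branch)
    # ancestor closure: clone k carries mutation i iff branch[i] on its root path
    on_path = np.zeros((K, K), dtype=bool)  # on_path[k, b]: b is ancestor-or-self of k
    for k in range(K):
        node = k
        while node != 0:
            on_path[k, node] = True
            node = parent[node]
    C_true = on_path[:, branch].T.astype(np.int8)  # (N, K)
    flips = rng.random(C_true.shape) < xi_true
    omega = np.where(flips, 1 - C_true, C_true).astype(np.int8)
    genotypes = CloneGenotypes(
        mutation_ids=[f"chr1:{1000 + i}:A:T" for i in range(N)],
        clone_ids=[f"clone{k + 1}" for k in range(K)],
        omega=omega,
    )
    return C_true, genotypes


def _cluster_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.explicit_sizes is not None:
        return np.asarray(cfg.explicit_sizes, dtype=int)
    n_multiplet_cells = int(round(cfg.M * cfg.multiplet_fraction))
    n_singletons = cfg.M - n_multiplet_cells
    n_mult = min(cfg.n_multiplet_clusters, n_multiplet_cells // 2)
    if n_mult == 0:
        return np.ones(cfg.M, dtype=int)
    # multiplet sizes: 2 + power-law tail, rescaled to the multiplet cell budget
    raw = rng.zipf(cfg.power_law_exponent, size=n_mult)
    sizes = 1 + np.minimum(raw, cfg.M)
    extra = n_multiplet_cells - sizes.sum()
    while extra != 0:
        idx = rng.integers(0, n_mult)
        if extra > 0:
            sizes[idx] += 1
            extra -= 1
        elif sizes[idx] > 2:
            sizes[idx] -= 1
            extra += 1
    return np.concatenate([sizes, np.ones(n_singletons, dtype=int)])


def simulate_cells(
    cfg: SimConfig, C_true: np.ndarray, rng: np.random.Generator
) -> tuple[AlleleCounts, InputClustering, DistanceMatrix, GroundTruth]:
    """Counts, input clustering and distances for one simulated cohort."""
    if cfg.coverage_rate == 0:
        raise ValueError("coverage_rate must be positive, otherwise no data")
    N, K = C_true.shape
    M = cfg.M
    sizes = _cluster_sizes(cfg, rng)
    Q = sizes.size
    true_cluster = np.repeat(np.arange(Q), sizes)
    clone_of_cluster = rng.integers(0, K, size=Q)
    clone_of_cell = clone_of_cluster[true_cluster]

    theta = cfg.theta_true
    if theta is None:
        a1, b1 = cfg.theta_dist
        theta = rng.beta(a1, b1, size=N)
    theta = np.asarray(theta, dtype=float)

    covered = rng.random((N, M)) < cfg.coverage_rate
    depth = np.where(
        covered, 1 + rng.poisson(max(cfg.depth_mean - 1.0, 0.0), size=(N, M)), 0
    )
    carries = C_true[:, clone_of_cell].astype(bool)  # (N, M)
    p_alt = np.where(carries, theta[:, None], cfg.theta0_true)
    alt = rng.binomial(depth, p_alt)

    counts = AlleleCounts(
        mutation_ids=[f"chr1:{1000 + i}:A:T" for i in range(N)],
        cell_ids=[f"cell{j:04d}" for j in range(M)],
        alt=sp.csr_matrix(alt),
        total=sp.csr_matrix(depth),
    )

    # input clustering: truth with a misclustered fraction moved elsewhere
    input_cluster = true_cluster.copy()
    n_move = int(round(cfg.misclustered_fraction * M))
    if n_move > 0 and Q > 1:
        occupancy = np.bincount(input_cluster, minlength=Q)
        movers = rng.choice(M, size=n_move, replace=False)
        for j in movers:
            if occupancy[input_cluster[j]] < 2:
                continue  # moving would empty the cluster; keep the partition
            choices = np.delete(np.arange(Q), true_cluster[j])
            target = rng.choice(choices)
            occupancy[input_cluster[j]] -= 1
            occupancy[target] += 1
            input_cluster[j] = target

    clustering = InputClustering(
        cell_ids=list(counts.cell_ids),
        cluster_ids=[f"bcr{q:04d}" for q in range(Q)],
        cluster_index=input_cluster,
    )

    # distances: 0 to own input cluster, small to the true cluster, larger noise
    # elsewhere — a BCR-like geometry in which misclustering is recoverable
    G = cfg.bcr_distance_scale * (1.0 + rng.random((M, Q)))
    G[np.arange(M), true_cluster] = 1.0
    G[np.arange(M), input_cluster] = 0.0
    distances = DistanceMatrix(G)

    truth = GroundTruth(
        C_true=C_true,
        clone_of_cluster=clone_of_cluster,
        cluster_of_cell=true_cluster,
        clone_of_cell=clone_of_cell,
        theta_true=theta,
        theta0_true=cfg.theta0_true,
        xi_true=cfg.xi_true,
    )
    return counts, clustering, distances, truth


def simulate_dataset(cfg: SimConfig) -> tuple[ClonalData, GroundTruth]:
    """Full generator: genotypes plus cohort, joined into a ClonalData.

    The join keeps the simulated axes intact (no filtering) so that truth
    indices remain aligned; mutations or cells without variant evidence are
    retained deliberately here — use :func:`cactus.data_model.join_axes` for
    the filtering behavior on real inputs.
    """
    rng = np.random.default_rng(cfg.seed)
    C_true, genotypes = simulate_genotypes(cfg.K, cfg.N, rng, cfg.xi_true)
    counts, clustering, distances, truth = simulate_cells(cfg, C_true, rng)
    data = ClonalData(
        genotypes=genotypes,
        counts=counts,
        clustering=clustering,
        distances=distances,
    )
    return data, truth


def enumerate_posterior(
    data: ClonalData,
    p: SwitchProbabilities,
    theta0: float,
    theta: np.ndarray,
    xi: float,
    max_states: float = 1e7,
) -> dict[str, np.ndarray]:
    """Exact marginals of I, T and the cell clone by exhaustive summation.

    With theta and xi clamped, sums the unnormalized joint
    ``P(C | omega, xi) P(I) P(T | p) P(A | D, C, I, T, theta)`` over all
    ``2^(N K)`` genotype matrices and ``K^Q`` cluster assignments; the sum
    over T factorizes per cell given (C, I).  Only feasible on tiny
    instances.
    """
    n, m, k, q = data.shape
    n_states = (k ** q) * (q ** m) * (2.0 ** (n * k))
    if n_states > max_states:
        raise ValueError(f"state space too large: {n_states:.3g} > {max_states:.3g}")

    log_p = p.log_p
    omega = data.genotypes.omega
    prior1 = np.abs(omega - xi)
    with np.errstate(divide="ignore"):
        lp1, lp0 = np.log(prior1), np.log1p(-prior1)

    log_weights = []
    pIs, pTs, pCells = [], [], []
    for c_bits in itertools.product((0, 1), repeat=n * k):
        C = np.array(c_bits, dtype=np.int8).reshape(n, k)
        lp_C = float(np.where(C == 1, lp1, lp0).sum())
        if not np.isfinite(lp_C):
            continue
        S = cell_clone_loglik(data, C, theta0, theta)  # (M, K)
        for I in itertools.product(range(k), repeat=q):
            I = np.array(I)
            logits = log_p + S[:, I]  # (M, Q): per-cell weight of each T_j
            per_cell = logsumexp(logits, axis=1)
            lw = lp_C - q * np.log(k) + float(per_cell.sum())
            post_T = np.exp(logits - per_cell[:, None])  # (M, Q)
            post_cell = np.zeros((m, k))
            np.add.at(post_cell.T, I, post_T.T)
            onehot_I = np.zeros((q, k))
            onehot_I[np.arange(q), I] = 1.0
            log_weights.append(lw)
            pIs.append(onehot_I)
            pTs.append(post_T)
            pCells.append(post_cell)

    log_weights = np.array(log_weights)
    w = np.exp(log_weights - logsumexp(log_weights))
    cluster_clone = np.tensordot(w, np.array(pIs), axes=1)
    cell_cluster = np.tensordot(w, np.array(pTs), axes=1)
    cell_clone = np.tensordot(w, np.array(pCells), axes=1)
    return {
        "cluster_clone_prob": cluster_clone,
        "cell_cluster_prob": cell_cluster,
        "cell_clone_prob": cell_clone,
    }
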