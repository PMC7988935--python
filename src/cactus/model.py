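"""Multi-chain Gibbs driver and the `CactusGibbs` estimator.

`CactusGibbs` follows the scikit-learn estimator protocol: hyperparameters in
``__init__``, inference in :meth:`fit`, results in trailing-underscore
attributes, `get_params`/`set_params` inherited from ``BaseEstimator``.
Module-level functions (:func:`initialize`, :func:`run_chain`,
:func:`summarize`, :func:`cell_clone_probabilities`,
:func:`align_clone_labels`) expose the individual steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from . import gibbs
from .cluster_prior import (
    SwitchProbabilities,
    switch_probabilities,
    uniform_switch_probabilities,
)
from .data_model import ClonalData, Hyperparameters
from .gibbs import GibbsState


@dataclass
class Trace:
    """Per-iteration records of one chain."""

    chain_index: int
    seed_entropy: tuple[int, ...]
    I: np.ndarray  # (iters, Q) int16
    xi: np.ndarray  # (iters,)
    theta0: np.ndarray  # (iters,)
    log_joint: np.ndarray  # (iters,)
    thin: int
    T: np.ndarray  # (iters // thin, M) int32
    C: np.ndarray  # (iters // thin, N, K) uint8
    final_state: GibbsState | None = None

    @property
    def n_iters(self) -> int:
        return self.I.shape[0]


@dataclass
class InferenceConfig:
    """Sampler budget and prior settings.

    Defaults mirror a full-scale run (20,000 iterations, 10 starting points,
    half discarded as burn-in); scale down for small problems.
    """

    max_iters: int = 20000
    n_chains: int = 10
    burn_in_frac: float = 0.5
    thin: int = 1
    master_seed: int = 0
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        if not 0.0 < self.burn_in_frac < 1.0:
            raise ValueError("burn_in_frac must lie in (0, 1)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.max_iters - self.burn_in(self.max_iters) < 1:
            raise ValueError("no post-burn-in samples under this configuration")

    def burn_in(self, iters: int | None = None) -> int:
        return int((iters if iters is not None else self.max_iters) * self.burn_in_frac)


@dataclass
class PosteriorSummary:
    """Posterior summaries of one inference run."""

    cluster_clone_prob: np.ndarray  # (Q, K)
    cell_clone_prob: np.ndarray  # (M, K)
    cell_cluster_prob: np.ndarray  # (M, Q)
    genotype_prob: np.ndarray  # (N, K)
    xi_samples: np.ndarray
    theta0_samples: np.ndarray
    map_clone_of_cluster: np.ndarray  # (Q,)
    map_clone_of_cell: np.ndarray  # (M,)
    map_cluster_of_cell: np.ndarray  # (M,)
    corrected_prevalence: np.ndarray  # (K,)
    best_chain: int
    chain_log_joint_means: np.ndarray
    cross_chain_max_disagreement: float

    def __post_init__(self) -> None:
        for rows in (self.cluster_clone_prob, self.cell_clone_prob, self.cell_cluster_prob):
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("posterior probability rows must sum to 1")
        if abs(self.corrected_prevalence.sum() - 1.0) > 1e-9:
            raise ValueError("corrected prevalences must sum to 1")


def _chain_rng(master_seed: int, chain_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, chain_index]))


def _initialize_from_rng(
    data: ClonalData, hp: Hyperparameters, rng: np.random.Generator
) -> GibbsState:
    n, _, k, q = data.shape
    a0, b0 = hp.v0
    a1, b1 = hp.v1
    k0, k1 = hp.kappa
    return GibbsState(
        I=rng.integers(0, k, size=q).astype(np.int64),
        T=data.clustering.cluster_index.copy(),
        C=data.genotypes.omega.astype(np.int8).copy(),
        theta0=a0 / (a0 + b0),
        theta=np.full(n, a1 / (a1 + b1)),
        xi=k0 / (k0 + k1),
    )


def initialize(
    data: ClonalData, config: InferenceConfig, chain_index: int
) -> GibbsState:
    """Initial state: T = input clustering, C = input genotypes, priors' means;
    I drawn uniformly at random, which is what differs across chains."""
    rng = _chain_rng(config.master_seed, chain_index)
    return _initialize_from_rng(data, config.hyperparameters, rng)


def run_chain(
    data: ClonalData,
    p: SwitchProbabilities,
    config: InferenceConfig,
    chain_index: int,
    n_iters: int | None = None,
    update_theta: bool = True,
    update_xi: bool = True,
    update_T: bool = True,
    update_C: bool = True,
    init_state: GibbsState | None = None,
) -> Trace:
    """Run one chain for ``n_iters`` sweeps; fully reproducible from
    (master_seed, chain_index)."""
    iters = n_iters if n_iters is not None else config.max_iters
    hp = config.hyperparameters
    rng = _chain_rng(config.master_seed, chain_index)
    if init_state is not None:
        state = init_state.copy()
        rng.integers(0, data.shape[2], size=data.shape[3])  # keep stream aligned
    else:
        state = _initialize_from_rng(data, hp, rng)
    n, m, k, q = data.shape
    thin = config.thin
    n_thin = (iters + thin - 1) // thin
    trace = Trace(
        chain_index=chain_index,
        seed_entropy=(config.master_seed, chain_index),
        I=np.empty((iters, q), dtype=np.int16),
        xi=np.empty(iters),
        theta0=np.empty(iters),
        log_joint=np.empty(iters),
        thin=thin,
        T=np.empty((n_thin, m), dtype=np.int32),
        C=np.empty((n_thin, n, k), dtype=np.uint8),
    )
    for it in range(iters):
        state = gibbs.sweep(
            state, data, p, hp, rng,
            update_theta=update_theta, update_xi=update_xi,
            update_T=update_T, update_C=update_C,
        )
        lj = gibbs.log_joint(state, data, p, hp)
        if not np.isfinite(lj):
            raise FloatingPointError(
                f"non-finite log joint at iteration {it} of chain {chain_index}: "
                f"xi={state.xi}, theta0={state.theta0}"
            )
        trace.I[it] = state.I
        trace.xi[it] = state.xi
        trace.theta0[it] = state.theta0
        trace.log_joint[it] = lj
        if it % thin == 0:
            trace.T[it // thin] = state.T
            trace.C[it // thin] = state.C
    trace.final_state = state
    return trace


def cell_clone_probabilities(trace: Trace, burn_in: int, n_clones: int) -> np.ndarray:
    """(M, K): fraction of retained iterations in which cell j's current
    corrected cluster is assigned to clone k (marginalizes over T)."""
    thin = trace.thin
    first = (burn_in + thin - 1) // thin
    T_kept = trace.T[first:]
    I_kept = trace.I[np.arange(first * thin, trace.n_iters, thin)]
    m = T_kept.shape[1]
    counts = np.zeros((m, n_clones))
    for Trow, Irow in zip(T_kept, I_kept):
        clones = Irow[Trow]
        counts[np.arange(m), clones] += 1
    return counts / T_kept.shape[0]


def summarize(
    traces: list[Trace], data: ClonalData, config: InferenceConfig
) -> PosteriorSummary:
    """Discard burn-in, pick the chain with the highest mean post-burn-in log
    joint, and report its posterior frequencies."""
    if not traces:
        raise ValueError("no completed chains to summarize")
    n, m, k, q = data.shape
    iters = traces[0].n_iters
    burn = config.burn_in(iters)
    means = np.array([t.log_joint[burn:].mean() for t in traces])
    best = int(np.argmax(means))
    t = traces[best]

    I_kept = t.I[burn:]
    cluster_clone = np.zeros((q, k))
    for qi in range(q):
        cluster_clone[qi] = np.bincount(I_kept[:, qi], minlength=k)
    cluster_clone /= I_kept.shape[0]

    thin = t.thin
    first = (burn + thin - 1) // thin
    T_kept = t.T[first:]
    cell_cluster = np.zeros((m, q))
    for j in range(m):
        cell_cluster[j] = np.bincount(T_kept[:, j], minlength=q)
    cell_cluster /= T_kept.shape[0]

    genotype_prob = t.C[first:].mean(axis=0)
    cell_clone = cell_clone_probabilities(t, burn, k)

    # cross-chain agreement on aligned cluster-to-clone posteriors
    disagreement = 0.0
    for other in traces:
        if other is t:
            continue
        other_cc = np.zeros((q, k))
        ok = other.I[burn:]
        for qi in range(q):
            other_cc[qi] = np.bincount(ok[:, qi], minlength=k)
        other_cc /= ok.shape[0]
        perm = align_clone_labels(genotype_prob, other.C[first:].mean(axis=0))
        disagreement = max(
            disagreement, float(np.abs(cluster_clone - other_cc[:, perm]).max())
        )

    map_cluster = cell_cluster.argmax(axis=1)
    map_clone_cluster = cluster_clone.argmax(axis=1)
    map_clone_cell = cell_clone.argmax(axis=1)
    prevalence = np.bincount(map_clone_cell, minlength=k) / m
    return PosteriorSummary(
        cluster_clone_prob=cluster_clone,
        cell_clone_prob=cell_clone,
        cell_cluster_prob=cell_cluster,
        genotype_prob=genotype_prob,
        xi_samples=t.xi[burn:].copy(),
        theta0_samples=t.theta0[burn:].copy(),
        map_clone_of_cluster=map_clone_cluster,
        map_clone_of_cell=map_clone_cell,
        map_cluster_of_cell=map_cluster,
        corrected_prevalence=prevalence,
        best_chain=best,
        chain_log_joint_means=means,
        cross_chain_max_disagreement=disagreement,
    )


def align_clone_labels(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` minimizing sum_k ||geno_a[:, k] - geno_b[:, perm[k]]||_1.

    Used to put two corrected-genotype sets on a common clone labeling before
    comparison.  Exhaustive search for K <= 8 (lexicographically smallest
    optimum on ties), Hungarian assignment otherwise.
    """
    geno_a = np.asarray(geno_a, dtype=float)
    geno_b = np.asarray(geno_b, dtype=float)
    if geno_a.shape != geno_b.shape:
        raise ValueError(f"shape mismatch: {geno_a.shape} vs {geno_b.shape}")
    k = geno_a.shape[1]
    cost = np.abs(geno_a[:, :, None] - geno_b[:, None, :]).sum(axis=0)  # (k_a, k_b)
    if k <= 8:
        best_perm, best_cost = None, np.inf
        for perm in itertools.permutations(range(k)):
            c = cost[np.arange(k), perm].sum()
            if c < best_cost - 1e-12:
                best_cost, best_perm = c, perm
        return np.array(best_perm)
    rows, cols = linear_sum_assignment(cost)
    return cols[np.argsort(rows)]


class CactusGibbs(BaseEstimator):
    """Cluster-to-clone assignment by Gibbs sampling.

    Assigns clusters of single cells (e.g. BCR clonotype clusters) to tumor
    clones from allele-specific transcript counts at mutated positions, while
    jointly correcting the input clone genotypes and the input clustering.

    Parameters
    ----------
    n_iters : int
        Gibbs sweeps per chain.
    n_chains : int
        Independent starting points; the chain with the highest mean
        post-burn-in log joint is reported.
    burn_in_frac : float
        Leading fraction of each chain discarded.
    thin : int
        Record the (large) T and C matrices every ``thin`` iterations.
    c : float
        Strength of the cluster prior: switch probabilities are the row-wise
        softmax of ``-c * G``.
    kappa, v0, v1 : (float, float)
        Beta-prior parameters for xi, theta0 and theta_i.
    fix_theta, fix_xi : optional
        Clamp theta = (theta0, theta_i vector) and/or xi instead of sampling
        them (used for exact-enumeration cross-checks).
    random_state : int
        Master seed; chain ``c`` uses the stream seeded by
        ``(random_state, c)``.

    Attributes
    ----------
    cluster_clone_prob_ : ndarray of shape (Q, K)
    cell_clone_prob_ : ndarray of shape (M, K)
    cell_cluster_prob_ : ndarray of shape (M, Q)
    genotype_prob_ : ndarray of shape (N, K)
    xi_samples_, theta0_samples_ : ndarray
    map_clone_of_cluster_, map_clone_of_cell_, map_cluster_of_cell_ : ndarray
    corrected_prevalence_ : ndarray of shape (K,)
    summary_ : PosteriorSummary
    traces_ : list of Trace
    """

    def __init__(
        self,
        n_iters: int = 20000,
        n_chains: int = 10,
        burn_in_frac: float = 0.5,
        thin: int = 1,
        c: float = 2.0,
        kappa: tuple[float, float] = (1.0, 9.0),
        v0: tuple[float, float] = (0.3, 29.7),
        v1: tuple[float, float] = (2.25, 2.65),
        fix_theta: tuple[float, np.ndarray] | None = None,
        fix_xi: float | None = None,
        keep_traces: bool = True,
        random_state: int = 0,
    ):
        self.n_iters = n_iters
        self.n_chains = n_chains
        self.burn_in_frac = burn_in_frac
        self.thin = thin
        self.c = c
        self.kappa = kappa
        self.v0 = v0
        self.v1 = v1
        self.fix_theta = fix_theta
        self.fix_xi = fix_xi
        self.keep_traces = keep_traces
        self.random_state = random_state

    def _config(self) -> InferenceConfig:
        return InferenceConfig(
            max_iters=self.n_iters,
            n_chains=self.n_chains,
            burn_in_frac=self.burn_in_frac,
            thin=self.thin,
            master_seed=self.random_state,
            hyperparameters=Hyperparameters(
                c=self.c, kappa=self.kappa, v0=self.v0, v1=self.v1
            ),
        )

    def fit(self, data: ClonalData, p: SwitchProbabilities | None = None):
        """Run the sampler on a joined dataset.

        ``p`` defaults to switch probabilities from ``data.distances`` when
        present, else to the uniform prior over clusters.
        """
        config = self._config()
        if p is None:
            if data.distances is not None:
                p = switch_probabilities(data.distances, self.c)
            else:
                p = uniform_switch_probabilities(
                    data.clustering.n_cells, data.clustering.n_clusters
                )
        update_theta, update_xi = self.fix_theta is None, self.fix_xi is None
        traces = []
        for chain in range(self.n_chains):
            init = None
            if not (update_theta and update_xi):
                init = initialize(data, config, chain)
                if self.fix_theta is not None:
                    init.theta0 = float(self.fix_theta[0])
                    init.theta = np.asarray(self.fix_theta[1], dtype=float)
                if self.fix_xi is not None:
                    init.xi = float(self.fix_xi)
            traces.append(
                run_chain(
                    data, p, config, chain,
                    update_theta=update_theta, update_xi=update_xi,
                    init_state=init,
                )
            )
        summary = summarize(traces, data, config)
        self.switch_probabilities_ = p
        self.summary_ = summary
        self.traces_ = traces if self.keep_traces else []
        self.cluster_clone_prob_ = summary.cluster_clone_prob
        self.cell_clone_prob_ = summary.cell_clone_prob
        self.cell_cluster_prob_ = summary.cell_cluster_prob
        self.genotype_prob_ = summary.genotype_prob
        self.xi_samples_ = summary.xi_samples
        self.theta0_samples_ = summary.theta0_samples
        self.map_clone_of_cluster_ = summary.map_clone_of_cluster
        self.map_clone_of_cell_ = summary.map_clone_of_cell
        self.map_cluster_of_cell_ = summary.map_cluster_of_cell
        self.corrected_prevalence_ = summary.corrected_prevalence
        return self

    def predict_proba(self) -> np.ndarray:
        """Posterior cell-to-clone probability matrix (M, K)."""
        return self.cell_clone_prob_

    def predict(self) -> np.ndarray:
        """MAP clone index per cell."""
        return self.map_clone_of_cell_
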