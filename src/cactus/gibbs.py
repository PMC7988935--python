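"""Conditional samplers of the cluster-to-clone assignment model.

Hidden variables:

* ``I`` (length Q)  — clone assigned to each cell cluster, uniform prior;
* ``T`` (length M)  — corrected cluster of each cell, categorical prior with
  switch probabilities ``p``;
* ``C`` (N x K)     — corrected clone genotypes; the prior probability that
  ``C[i,k] = 1`` given the input genotype ``omega[i,k]`` and error rate
  ``xi`` is ``|omega[i,k] - xi|``;
* ``theta0``, ``theta[i]`` — binomial success probabilities of observing the
  alternative allele in a non-carrying / carrying cell, with beta priors;
* ``xi``            — genotype error rate, beta prior.

The read-count likelihood at a covered position is
``Binom(A | D, theta_i)`` when the assigned clone carries the mutation and
``Binom(A | D, theta0)`` otherwise; uncovered entries (D = 0) contribute a
factor of one.  Each sampler below draws from the exact full conditional,
evaluated in log space with max-subtraction.  One :func:`sweep` updates, in
order: I (all clusters), theta, T (all cells), C (all entries), xi.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import binom

from .cluster_prior import SwitchProbabilities
from .data_model import ClonalData, Hyperparameters

# log-probability floor: differences below exp(-745) underflow to 0 anyway
LOG_FLOOR = -745.0


@dataclass
class GibbsState:
    """Current values of all hidden variables (0-based indices)."""

    I: np.ndarray  # (Q,) clone index per cluster
    T: np.ndarray  # (M,) cluster index per cell
    C: np.ndarray  # (N, K) corrected genotypes
    theta0: float
    theta: np.ndarray  # (N,)
    xi: float

    def copy(self) -> "GibbsState":
        return replace(
            self,
            I=self.I.copy(),
            T=self.T.copy(),
            C=self.C.copy(),
            theta=self.theta.copy(),
        )


@dataclass
class SufficientStats:
    """Beta-binomial sufficient statistics for the theta update.

    ``u0``/``v0`` pool alt/ref counts over covered entries whose assigned
    clone does not carry the mutation; ``u[i]``/``v[i]`` pool the carrying
    entries per position.  Every covered read lands on exactly one side.
    """

    u0: float
    v0: float
    u: np.ndarray
    v: np.ndarray


def loglik_entry(
    a: int, d: int, carries_mut: int, theta0: float, theta_i: float
) -> float:
    """Log binomial likelihood of one count entry; 0 when uncovered."""
    for t in (theta0, theta_i):
        if not 0.0 < t < 1.0:
            raise ValueError(f"theta must lie strictly in (0, 1), got {t}")
    if not 0 <= a <= d:
        raise ValueError(f"need 0 <= alt <= total, got alt={a}, total={d}")
    if d == 0:
        return 0.0
    p = theta_i if carries_mut else theta0
    return float(binom.logpmf(a, d, p))


def _entry_logliks(
    data: ClonalData, theta0: float, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per covered entry: log Binom under theta0 and under theta_row."""
    a, d, row = data.a, data.d, data.row
    log_coef = gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)
    l0 = log_coef + a * np.log(theta0) + (d - a) * np.log1p(-theta0)
    ti = theta[row]
    l1 = log_coef + a * np.log(ti) + (d - a) * np.log1p(-ti)
    return l0, l1


def cell_clone_loglik(
    data: ClonalData, C: np.ndarray, theta0: float, theta: np.ndarray
) -> np.ndarray:
    """(M, K) matrix: log-likelihood of each cell's counts under each clone."""
    l0, l1 = _entry_logliks(data, theta0, theta)
    _, m, k, _ = data.shape
    base = np.bincount(data.col, weights=l0, minlength=m)  # all-theta0 baseline
    delta = l1 - l0
    S = np.zeros((m, k))
    np.add.at(S, data.col, delta[:, None] * C[data.row, :])
    return base[:, None] + S


def _sample_rows(log_w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical index per row of unnormalized log weights."""
    log_w = np.clip(log_w, LOG_FLOOR, None)
    log_w = log_w - log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    cdf = np.cumsum(w, axis=1)
    u = rng.random(log_w.shape[0]) * cdf[:, -1]
    return (u[:, None] > cdf).sum(axis=1)


def conditional_I_logprob(state: GibbsState, data: ClonalData) -> np.ndarray:
    """(Q, K) normalized log conditional of each cluster's clone assignment.

    Cells enter the product through their *corrected* membership ``T``; the
    prior over clones is uniform, so an empty cluster yields a uniform row.
    """
    S = cell_clone_loglik(data, state.C, state.theta0, state.theta)
    _, _, k, q = data.shape
    logp = np.zeros((q, k))
    np.add.at(logp, state.T, S)
    return logp - logsumexp(logp, axis=1, keepdims=True)


def sample_I(
    state: GibbsState, data: ClonalData, rng: np.random.Generator
) -> np.ndarray:
    S = cell_clone_loglik(data, state.C, state.theta0, state.theta)
    _, _, k, q = data.shape
    logp = np.zeros((q, k))
    np.add.at(logp, state.T, S)
    return _sample_rows(logp, rng)


def theta_stats(state: GibbsState, data: ClonalData) -> SufficientStats:
    """Pool alt/ref counts by whether the cell's assigned clone carries i."""
    n = data.shape[0]
    clone_of_cell = state.I[state.T]
    carries = state.C[data.row, clone_of_cell[data.col]].astype(float)
    ref = data.d - data.a
    u = np.bincount(data.row, weights=data.a * carries, minlength=n)
    v = np.bincount(data.row, weights=ref * carries, minlength=n)
    return SufficientStats(
        u0=float(np.sum(data.a * (1 - carries))),
        v0=float(np.sum(ref * (1 - carries))),
        u=u,
        v=v,
    )


def sample_theta(
    stats: SufficientStats, hp: Hyperparameters, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Conjugate beta draws for theta0 and every theta_i."""
    a0, b0 = hp.v0
    a1, b1 = hp.v1
    theta0 = rng.beta(a0 + stats.u0, b0 + stats.v0)
    theta = rng.beta(a1 + stats.u, b1 + stats.v)
    return float(theta0), theta


def conditional_T_logprob(
    state: GibbsState, data: ClonalData, p: SwitchProbabilities
) -> np.ndarray:
    """(M, Q) normalized log conditional of each cell's corrected cluster."""
    S = cell_clone_loglik(data, state.C, state.theta0, state.theta)
    logits = p.log_p + S[:, state.I]
    return logits - logsumexp(logits, axis=1, keepdims=True)


def sample_T(
    state: GibbsState,
    data: ClonalData,
    p: SwitchProbabilities,
    rng: np.random.Generator,
) -> np.ndarray:
    S = cell_clone_loglik(data, state.C, state.theta0, state.theta)
    return _sample_rows(p.log_p + S[:, state.I], rng)


def conditional_C_prob(state: GibbsState, data: ClonalData) -> np.ndarray:
    """(N, K) probability that each corrected-genotype entry equals 1.

    Entry (i, k) weighs the prior ``|omega - xi|`` against the likelihoods of
    the counts at position i in all cells currently assigned to clone k.
    """
    l0, l1 = _entry_logliks(data, state.theta0, state.theta)
    n, _, k, _ = data.shape
    clone_of_cell = state.I[state.T]
    k_ent = clone_of_cell[data.col]
    flat = data.row * k + k_ent
    L0 = np.bincount(flat, weights=l0, minlength=n * k).reshape(n, k)
    L1 = np.bincount(flat, weights=l1, minlength=n * k).reshape(n, k)
    prior1 = np.abs(data.genotypes.omega - state.xi)
    # log-odds of C=1; degenerate priors (xi = 0 or 1) short-circuit exactly
    with np.errstate(divide="ignore"):
        log_odds = np.log(prior1) - np.log1p(-prior1) + np.clip(L1 - L0, LOG_FLOOR, -LOG_FLOOR)
    prob = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700.0, 700.0)))
    prob[prior1 == 0.0] = 0.0
    prob[prior1 == 1.0] = 1.0
    return prob


def sample_C(
    state: GibbsState, data: ClonalData, rng: np.random.Generator
) -> np.ndarray:
    prob = conditional_C_prob(state, data)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def sample_xi(
    C: np.ndarray,
    omega: np.ndarray,
    kappa: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Beta draw from mismatch/match counts between corrected and input genotypes."""
    mismatches = int(np.sum(C != omega))
    matches = C.size - mismatches
    k0, k1 = kappa
    return float(rng.beta(k0 + mismatches, k1 + matches))


def log_joint(
    state: GibbsState, data: ClonalData, p: SwitchProbabilities, hp: Hyperparameters
) -> float:
    """Unnormalized log joint density of data and current hidden state."""
    n, m, k, q = data.shape
    S = cell_clone_loglik(data, state.C, state.theta0, state.theta)
    ll = float(S[np.arange(m), state.I[state.T]].sum())
    lp_I = -q * np.log(k)
    lp_T = float(p.log_p[np.arange(m), state.T].sum())
    prior1 = np.abs(data.genotypes.omega - state.xi)
    pc = np.where(state.C == 1, prior1, 1.0 - prior1)
    with np.errstate(divide="ignore"):
        lp_C = float(np.sum(np.clip(np.log(pc), LOG_FLOOR, None)))
    a0, b0 = hp.v0
    a1, b1 = hp.v1
    k0, k1 = hp.kappa
    lp_theta0 = (a0 - 1) * np.log(state.theta0) + (b0 - 1) * np.log1p(-state.theta0) - betaln(a0, b0)
    lp_theta = float(
        np.sum((a1 - 1) * np.log(state.theta) + (b1 - 1) * np.log1p(-state.theta))
        - n * betaln(a1, b1)
    )
    lp_xi = (k0 - 1) * np.log(state.xi) + (k1 - 1) * np.log1p(-state.xi) - betaln(k0, k1)
    return ll + lp_I + lp_T + lp_C + lp_theta0 + lp_theta + float(lp_xi)


def sweep(
    state: GibbsState,
    data: ClonalData,
    p: SwitchProbabilities,
    hp: Hyperparameters,
    rng: np.random.Generator,
    update_theta: bool = True,
    update_xi: bool = True,
    update_T: bool = True,
    update_C: bool = True,
) -> GibbsState:
    """One systematic-scan Gibbs sweep in the order I, theta, T, C, xi.

    The ``update_*`` switches clamp the corresponding variables, used by the
    enumeration cross-checks (theta, xi fixed) and prior-only runs.
    """
    state.I = sample_I(state, data, rng)
    if update_theta:
        stats = theta_stats(state, data)
        state.theta0, state.theta = sample_theta(stats, hp, rng)
    if update_T:
        state.T = sample_T(state, data, p, rng)
    if update_C:
        state.C = sample_C(state, data, rng)
    if update_xi:
        state.xi = sample_xi(state.C, data.genotypes.omega, hp.kappa, rng)
    return state
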