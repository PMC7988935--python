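"""Independent reference implementations used only as test oracles.

Deliberately written against the math directly (plain loops / dense arrays,
no code shared with the package) so that agreement with the package is a
genuine dual-route check: a brute-force enumerator of the joint posterior, a
per-cell (cardelino-style) Gibbs sampler without the cluster layer, and a
pair-counting adjusted Rand index.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom as sp_binom


def binom_pmf(a: int, d: int, p: float) -> float:
    return float(sp_binom.pmf(a, d, p))


def brute_force_posterior(
    A: np.ndarray,
    D: np.ndarray,
    omega: np.ndarray,
    p: np.ndarray,
    theta0: float,
    theta: np.ndarray,
    xi: float,
) -> dict[str, np.ndarray]:
    """Exact marginals by triple loop over all (C, I, T) joint states."""
    N, M = A.shape
    K = omega.shape[1]
    Q = p.shape[1]
    pI = np.zeros((Q, K))
    pT = np.zeros((M, Q))
    pCell = np.zeros((M, K))
    total = 0.0
    for c_bits in itertools.product((0, 1), repeat=N * K):
        C = np.array(c_bits).reshape(N, K)
        prior_c = 1.0
        for i in range(N):
            for k in range(K):
                p1 = abs(omega[i, k] - xi)
                prior_c *= p1 if C[i, k] == 1 else (1.0 - p1)
        for I in itertools.product(range(K), repeat=Q):
            for T in itertools.product(range(Q), repeat=M):
                w = prior_c * (1.0 / K) ** Q
                for j in range(M):
                    w *= p[j, T[j]]
                    clone = I[T[j]]
                    for i in range(N):
                        if D[i, j] > 0:
                            th = theta[i] if C[i, clone] == 1 else theta0
                            w *= binom_pmf(A[i, j], D[i, j], th)
                total += w
                for q in range(Q):
                    pI[q, I[q]] += w
                for j in range(M):
                    pT[j, T[j]] += w
                    pCell[j, I[T[j]]] += w
    return {
        "cluster_clone_prob": pI / total,
        "cell_cluster_prob": pT / total,
        "cell_clone_prob": pCell / total,
    }


def percell_gibbs_posterior(
    A: np.ndarray,
    D: np.ndarray,
    omega: np.ndarray,
    kappa: tuple[float, float],
    v0: tuple[float, float],
    v1: tuple[float, float],
    n_iters: int,
    burn_in: int,
    seed: int,
) -> np.ndarray:
    """Per-cell clone-assignment Gibbs sampler (no cluster layer).

    Latents: Z_j (clone of cell j, uniform prior), theta0/theta (beta priors),
    C (prior |omega - xi|), xi (beta prior).  Returns the (M, K) posterior
    frequency of Z from the retained iterations.
    """
    rng = np.random.default_rng(seed)
    N, M = A.shape
    K = omega.shape[1]
    a0, b0 = v0
    a1, b1 = v1
    k0, k1 = kappa
    Z = rng.integers(0, K, size=M)
    C = omega.copy().astype(int)
    theta0 = a0 / (a0 + b0)
    theta = np.full(N, a1 / (a1 + b1))
    xi = k0 / (k0 + k1)
    log_coef = gammaln(D + 1) - gammaln(A + 1) - gammaln(D - A + 1)
    counts = np.zeros((M, K))
    for it in range(n_iters):
        l0 = np.where(D > 0, log_coef + A * math.log(theta0) + (D - A) * math.log1p(-theta0), 0.0)
        l1 = np.where(
            D > 0,
            log_coef + A * np.log(theta)[:, None] + (D - A) * np.log1p(-theta)[:, None],
            0.0,
        )
        # Z_j | rest
        for j in range(M):
            logw = np.zeros(K)
            for k in range(K):
                logw[k] = np.sum(np.where(C[:, k] == 1, l1[:, j], l0[:, j]))
            w = np.exp(logw - logw.max())
            Z[j] = rng.choice(K, p=w / w.sum())
        # theta | rest
        carries = C[:, Z].astype(bool)  # (N, M)
        cov = D > 0
        u0 = A[cov & ~carries].sum()
        w0 = (D - A)[cov & ~carries].sum()
        theta0 = rng.beta(a0 + u0, b0 + w0)
        for i in range(N):
            sel = cov[i] & carries[i]
            theta[i] = rng.beta(a1 + A[i, sel].sum(), b1 + (D - A)[i, sel].sum())
        # C | rest (recompute likelihood terms at the fresh theta)
        l0 = np.where(D > 0, log_coef + A * math.log(theta0) + (D - A) * math.log1p(-theta0), 0.0)
        l1 = np.where(
            D > 0,
            log_coef + A * np.log(theta)[:, None] + (D - A) * np.log1p(-theta)[:, None],
            0.0,
        )
        for i in range(N):
            for k in range(K):
                cells = np.flatnonzero(Z == k)
                log1 = math.log(abs(omega[i, k] - xi)) + l1[i, cells].sum()
                log0 = math.log(1.0 - abs(omega[i, k] - xi)) + l0[i, cells].sum()
                mx = max(log0, log1)
                p1 = math.exp(log1 - mx) / (math.exp(log0 - mx) + math.exp(log1 - mx))
                C[i, k] = 1 if rng.random() < p1 else 0
        # xi | rest
        mism = int((C != omega).sum())
        xi = rng.beta(k0 + mism, k1 + C.size - mism)
        if it >= burn_in:
            counts[np.arange(M), Z] += 1
    return counts / (n_iters - burn_in)


def pair_counting_ari(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index by explicit enumeration of item pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            ss += sa and sb
            sd += sa and not sb
            ds += sb and not sa
            dd += not sa and not sb
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 0.0
    return (ss - expected) / (max_index - expected)
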