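import math

import numpy as np
import pytest

from cactus import Hyperparameters, uniform_switch_probabilities
from cactus.gibbs import (
    GibbsState,
    SufficientStats,
    conditional_C_prob,
    conditional_I_logprob,
    conditional_T_logprob,
    loglik_entry,
    sample_theta,
    sample_xi,
    theta_stats,
)
from conftest import make_data


def _state(I, T, C, theta0=0.01, theta=None, xi=0.1):
    C = np.asarray(C)
    theta = np.full(C.shape[0], 0.5) if theta is None else np.asarray(theta, float)
    return GibbsState(
        I=np.asarray(I), T=np.asarray(T), C=C.astype(np.int8),
        theta0=theta0, theta=theta, xi=xi,
    )


class TestLoglikEntry:
    @pytest.mark.parametrize(
        "a, d, carries, theta0, theta_i, expected",
        [
            (0, 0, 1, 0.5, 0.5, 0.0),  # uncovered -> likelihood 1
            (2, 2, 1, 0.01, 0.5, math.log(0.25)),
            (1, 3, 0, 0.01, 0.5, math.log(3 * 0.01 * 0.99**2)),
        ],
    )
    def test_values(self, a, d, carries, theta0, theta_i, expected):
        assert loglik_entry(a, d, carries, theta0, theta_i) == pytest.approx(expected)

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            loglik_entry(1, 2, 1, 0.5, 1.0)


class TestConditionalI:
    def test_two_clone_worked_case(self):
        # one cell, one covered position A=2,D=2; clone 0 non-carrier,
        # clone 1 carrier: P(I=1) = 0.25 / (0.25 + 0.0001)
        data = make_data(
            omega=[[0, 1]], A=[[2]], D=[[2]], cluster_index=[0]
        )
        st = _state(I=[0], T=[0], C=[[0, 1]], theta0=0.01, theta=[0.5])
        p = np.exp(conditional_I_logprob(st, data))[0]
        assert p[1] == pytest.approx(0.25 / (0.25 + 0.01**2), rel=1e-9)

    def test_identical_genotype_columns_give_uniform(self):
        data = make_data(
            omega=[[1, 1]], A=[[2]], D=[[3]], cluster_index=[0]
        )
        st = _state(I=[0], T=[0], C=[[1, 1]])
        p = np.exp(conditional_I_logprob(st, data))
        np.testing.assert_allclose(p, 0.5)

    def test_empty_cluster_is_uniform_prior(self):
        data = make_data(
            omega=[[0, 1], [1, 0]], A=[[1], [0]], D=[[2], [1]],
            cluster_index=[0],
        )
        # grow to 2 clusters; cluster 1 holds no cell under T
        data.clustering.cluster_ids.append("q_extra")
        st = _state(I=[0, 1], T=[0], C=[[0, 1], [1, 0]])
        logp = conditional_I_logprob(st, data)
        np.testing.assert_allclose(np.exp(logp[1]), 0.5)

    def test_scale_invariance_of_normalization(self):
        # multiplying all likelihood terms by a constant = adding a constant
        # in log space; the normalized conditional is unchanged
        data = make_data(omega=[[0, 1]], A=[[3]], D=[[5]], cluster_index=[0])
        st = _state(I=[0], T=[0], C=[[0, 1]], theta0=0.2, theta=[0.7])
        base = conditional_I_logprob(st, data)
        S_logits = base + 123.456  # unnormalized shift
        renorm = S_logits - np.log(np.exp(S_logits).sum(axis=1, keepdims=True))
        np.testing.assert_allclose(np.exp(base), np.exp(renorm), atol=1e-9)


class TestThetaStats:
    def test_all_noncarrying_pools_into_background(self):
        data = make_data(
            omega=[[0, 0]], A=[[1, 2]], D=[[2, 3]], cluster_index=[0, 0]
        )
        st = _state(I=[0], T=[0, 0], C=[[0, 0]])
        s = theta_stats(st, data)
        assert s.u0 == 3 and s.v0 == 2
        assert s.u.sum() == 0 and s.v.sum() == 0

    def test_hand_worked_mixed_case(self):
        # 2 positions x 2 cells, both cells on a clone with C column [1, 0]
        data = make_data(
            omega=[[1, 0], [0, 0]],
            A=[[1, 0], [2, 1]],
            D=[[2, 1], [2, 2]],
            cluster_index=[0, 1],
        )
        st = _state(I=[0, 0], T=[0, 1], C=[[1, 0], [0, 0]])
        s = theta_stats(st, data)
        assert s.u[0] == 1 and s.v[0] == 2
        assert s.u[1] == 0 and s.v[1] == 0
        assert s.u0 == 3 and s.v0 == 1

    def test_partition_identity(self, rng):
        # every covered read lands on exactly one side of the split
        A = rng.integers(0, 3, size=(4, 6))
        D = A + rng.integers(0, 3, size=(4, 6))
        C = rng.integers(0, 2, size=(4, 3))
        data = make_data(np.ones((4, 3)), A, D, np.array([0, 0, 1, 1, 2, 2]))
        st = _state(I=[0, 2, 1], T=data.clustering.cluster_index, C=C)
        s = theta_stats(st, data)
        assert s.u0 + s.v0 + s.u.sum() + s.v.sum() == data.d.sum()


class TestSampleTheta:
    def test_posterior_parameters_match_conjugate_form(self):
        # with u0=10, v0=990 and a flat prior the update is Beta(11, 991);
        # identical seeds make the parameter check exact
        hp = Hyperparameters(v0=(1.0, 1.0), v1=(2.0, 3.0))
        stats = SufficientStats(u0=10, v0=990, u=np.array([4.0]), v=np.array([6.0]))
        seed = 4242
        theta0, theta = sample_theta(stats, hp, np.random.default_rng(seed))
        ref = np.random.default_rng(seed)
        assert theta0 == pytest.approx(ref.beta(11.0, 991.0), rel=1e-12)
        assert theta[0] == pytest.approx(ref.beta(6.0, 9.0), rel=1e-12)

    def test_no_data_draws_from_prior(self, rng):
        hp = Hyperparameters(v1=(2.25, 2.65))
        stats = SufficientStats(u0=0, v0=0, u=np.zeros(1), v=np.zeros(1))
        draws = np.array([sample_theta(stats, hp, rng)[1][0] for _ in range(4000)])
        prior_mean = 2.25 / (2.25 + 2.65)
        assert draws.mean() == pytest.approx(prior_mean, abs=0.02)

    def test_large_sample_posterior_mean(self, rng):
        hp = Hyperparameters(v1=(2.25, 2.65))
        stats = SufficientStats(
            u0=0, v0=0, u=np.array([4500.0]), v=np.array([5500.0])
        )
        draws = np.array([sample_theta(stats, hp, rng)[1][0] for _ in range(10000)])
        analytic = (2.25 + 4500) / (2.25 + 2.65 + 10000)
        assert draws.mean() == pytest.approx(analytic, abs=0.01)


class TestConditionalT:
    def test_uncovered_cell_draws_from_prior(self):
        data = make_data(
            omega=[[0, 1]], A=[[0, 1]], D=[[0, 2]], cluster_index=[0, 1]
        )
        p = uniform_switch_probabilities(2, 2)
        p.p[:] = [[0.3, 0.7], [0.3, 0.7]]
        st = _state(I=[0, 1], T=[0, 1], C=[[0, 1]])
        post = np.exp(conditional_T_logprob(st, data, p))
        np.testing.assert_allclose(post[0], [0.3, 0.7], atol=1e-12)

    def test_same_clone_everywhere_draws_from_prior(self):
        data = make_data(
            omega=[[0, 1]], A=[[2, 1]], D=[[2, 2]], cluster_index=[0, 1]
        )
        p = uniform_switch_probabilities(2, 2)
        p.p[:] = [[0.9, 0.1], [0.2, 0.8]]
        st = _state(I=[1, 1], T=[0, 1], C=[[0, 1]])
        post = np.exp(conditional_T_logprob(st, data, p))
        np.testing.assert_allclose(post, p.p, atol=1e-12)

    def test_two_cluster_worked_case(self):
        # p = [0.5, 0.5], likelihoods [0.0001, 0.25] -> [0.0004, 0.9996]
        data = make_data(
            omega=[[0, 1]], A=[[2]], D=[[2]], cluster_index=[0]
        )
        data.clustering.cluster_ids.append("q1")
        p = uniform_switch_probabilities(1, 2)
        st = _state(I=[0, 1], T=[0], C=[[0, 1]], theta0=0.01, theta=[0.5])
        post = np.exp(conditional_T_logprob(st, data, p))[0]
        np.testing.assert_allclose(post, [0.0004, 0.9996], atol=5e-5)


class TestConditionalC:
    def test_no_assigned_cells_returns_prior(self):
        data = make_data(omega=[[1, 0]], A=[[1]], D=[[2]], cluster_index=[0])
        st = _state(I=[0], T=[0], C=[[1, 0]], xi=0.2)
        prob = conditional_C_prob(st, data)
        # clone 1 has no assigned cells: prior |omega - xi| = |0 - 0.2|
        assert prob[0, 1] == pytest.approx(0.2)

    def test_degenerate_xi_zero(self):
        data = make_data(omega=[[0, 0]], A=[[2]], D=[[2]], cluster_index=[0])
        st = _state(I=[0], T=[0], C=[[0, 0]], xi=0.0)
        prob = conditional_C_prob(st, data)
        assert prob[0, 0] == 0.0 and prob[0, 1] == 0.0

    def test_worked_two_term_ratio(self):
        # omega=0, xi=0.1, one assigned cell A=3, D=3, theta_i=0.5, theta0=0.01
        data = make_data(omega=[[0, 0]], A=[[3]], D=[[3]], cluster_index=[0])
        st = _state(I=[0], T=[0], C=[[0, 0]], theta0=0.01, theta=[0.5], xi=0.1)
        prob = conditional_C_prob(st, data)
        expected = 0.1 * 0.125 / (0.1 * 0.125 + 0.9 * 1e-6)
        assert prob[0, 0] == pytest.approx(expected, abs=5e-6)


class TestSampleXi:
    @pytest.mark.parametrize(
        "mismatches, total, kappa, expected",
        [
            (0, 8, (1.0, 1.0), (1.0, 9.0)),
            (8, 8, (1.0, 1.0), (9.0, 1.0)),
            (3, 8, (2.0, 18.0), (5.0, 23.0)),
        ],
    )
    def test_beta_parameters(self, mismatches, total, kappa, expected):
        omega = np.zeros((2, 4), dtype=int)
        C = omega.copy()
        C.flat[:mismatches] = 1
        seed = 77
        draw = sample_xi(C, omega, kappa, np.random.default_rng(seed))
        reference = np.random.default_rng(seed).beta(*expected)
        assert draw == pytest.approx(reference, rel=1e-12)

    def test_moments_match_beta(self, rng):
        omega = np.zeros((2, 4), dtype=int)
        C = omega.copy()
        C.flat[:2] = 1  # 2 mismatches, 6 matches
        draws = np.array(
            [sample_xi(C, omega, (1.0, 9.0), rng) for _ in range(10000)]
        )
        a, b = 3.0, 15.0
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se + 1e-4
        assert draws.var() == pytest.approx(var, rel=0.1)
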