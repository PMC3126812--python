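import numpy as np
import pytest
from math import comb

import mcwr


def geometric_lifetime_moment(d: float, m: int, tmax: int = 2000) -> float:
    """E[T^m] for T ~ geometric on {1, 2, ...} with stopping probability d,
    by exhaustive summation — the enumeration oracle."""
    t = np.arange(1, tmax + 1)
    return float(np.sum(d * (1 - d) ** (t - 1) * t.astype(float) ** m))


def solve_moments(P, R, k):
    """Direct linear-solve for the recursion fixed point — an algebraic
    oracle independent of the backward iteration."""
    n = P.shape[0]
    s = n - 1
    ones = np.ones(n)
    full = [ones]
    out = []
    for m in range(1, k + 1):
        rhs = (P * R[m]).T @ ones
        for j in range(1, m):
            rhs = rhs + comb(m, j) * ((P * R[m - j]).T @ full[j])
        x = np.linalg.solve(np.eye(s) - P[:s, :s].T, rhs[:s])
        v = np.zeros(n)
        v[:s] = x
        full.append(v)
        out.append(x)
    return out


class TestAccumulateMoments:
    def test_zero_rewards_give_zero_moments(self, stage_u):
        P = mcwr.build_absorbing_chain(stage_u)
        R = mcwr.fixed_rewards(np.zeros(6), k=3)
        m = mcwr.accumulate_moments(P, R, k=3)
        for j in (1, 2, 3):
            assert np.all(m[j] == 0)

    def test_geometric_closed_form(self):
        # single stage, survival 0.5, unit reward on every transition:
        # lifetime reward equals the geometric lifetime itself
        P = mcwr.build_absorbing_chain(np.array([[0.5]]))
        R = mcwr.fixed_rewards([1.0], k=3)
        m = mcwr.accumulate_moments(P, R, k=3, tol=1e-13)
        d = 0.5
        closed = [1 / d, (2 - d) / d ** 2, (6 - 6 * d + d ** 2) / d ** 3]
        for j, want in enumerate(closed, start=1):
            assert abs(m[j][0] - want) < 1e-10
            assert abs(want - geometric_lifetime_moment(d, j)) < 1e-10

    @pytest.mark.parametrize("seed", [2, 9])
    def test_matches_linear_solve_oracle(self, seed):
        U = mcwr.random_stage_model(4, seed=seed)
        P = mcwr.build_absorbing_chain(U)
        R = mcwr.poisson_rewards([0.0, 0.3, 1.0, 4.0], k=4)
        m = mcwr.accumulate_moments(P, R, k=4, tol=1e-13)
        direct = solve_moments(P, R, 4)
        for j in (1, 2, 3, 4):
            assert np.allclose(m[j], direct[j - 1], rtol=1e-9)

    def test_monotone_first_moment_in_horizon(self, stage_u):
        P = mcwr.build_absorbing_chain(stage_u)
        R = mcwr.poisson_rewards([0, 0, 0, 0, 0, 5.0], k=1)
        M1 = (P * R[1]).T @ np.ones(7)
        rho, prev = np.zeros(7), None
        for _ in range(30):
            prev, rho = rho, M1 + P.T @ rho
            assert np.all(rho >= prev - 1e-12)

    def test_nonconvergence_reports_residual(self):
        P = mcwr.build_absorbing_chain(np.array([[0.9]]))
        R = mcwr.fixed_rewards([1.0], k=2)
        with pytest.raises(RuntimeError, match="converge"):
            mcwr.accumulate_moments(P, R, k=2, tol=1e-12, max_iter=5)

    def test_order_mismatch_rejected(self):
        P = mcwr.build_absorbing_chain(np.array([[0.5]]))
        R = mcwr.fixed_rewards([1.0], k=2)
        with pytest.raises(ValueError, match="order"):
            mcwr.accumulate_moments(P, R, k=3)

    def test_variance_nonnegative_invariant(self, stage_u):
        P = mcwr.build_absorbing_chain(stage_u)
        R = mcwr.poisson_rewards([0, 0, 0, 0.5, 2.0, 10.0], k=2)
        m = mcwr.accumulate_moments(P, R, k=2)
        assert np.all(m[2] >= m[1] ** 2 - 1e-10)


class TestLifetimeStatistics:
    def test_geometric_statistics(self):
        P = mcwr.build_absorbing_chain(np.array([[0.5]]))
        m = mcwr.accumulate_moments(P, mcwr.fixed_rewards([1.0], k=3), k=3,
                                    tol=1e-13)
        st = mcwr.lifetime_statistics(m).iloc[0]
        assert np.isclose(st["var"], 2.0)
        assert np.isclose(st["sd"], np.sqrt(2.0))
        assert np.isclose(st["cv"], np.sqrt(2.0) / 2)
        # geometric skewness (2 - d) / sqrt(1 - d) at d = 0.5
        assert np.isclose(st["skew"], 1.5 / np.sqrt(0.5))

    def test_deterministic_reward_degenerate_stats(self):
        # certain death in one step, fixed reward 5 on the death transition
        P = mcwr.build_absorbing_chain(np.array([[0.0]]))
        m = mcwr.accumulate_moments(P, mcwr.fixed_rewards([5.0], k=3), k=3)
        st = mcwr.lifetime_statistics(m).iloc[0]
        assert st["mean"] == 5.0 and st["var"] == 0.0
        assert np.isnan(st["skew"])
        assert st["cv"] == 0.0  # defined: zero spread around a positive mean

    def test_single_step_poisson_reward_has_cv_equal_skew(self):
        # death after one step with a Poisson reward: lifetime reproduction
        # is Poisson, whose CV equals its skewness
        P = mcwr.build_absorbing_chain(np.array([[0.0]]))
        m = mcwr.accumulate_moments(P, mcwr.poisson_rewards([2.5], k=3), k=3)
        st = mcwr.lifetime_statistics(m).iloc[0]
        assert np.isclose(st["cv"], st["skew"])
        assert np.isclose(st["cv"], 1 / np.sqrt(2.5))

    def test_remaining_reproduction_table(self, leslie_model):
        U, F = leslie_model
        P = mcwr.build_absorbing_chain(U)
        m = mcwr.accumulate_moments(P, mcwr.fixed_rewards(F[0], k=3), k=3)
        tab = mcwr.remaining_reproduction_by_stage(m)
        assert list(tab.index) == [f"stage_{i}" for i in (1, 2, 3, 4)]
        # from-birth statistics are the stage-1 row by definition
        assert tab.iloc[0]["mean"] == m[1][0]

    def test_single_stage_table_has_one_row(self):
        P = mcwr.build_absorbing_chain(np.array([[0.5]]))
        m = mcwr.accumulate_moments(P, mcwr.fixed_rewards([1.0], k=3), k=3)
        assert len(mcwr.remaining_reproduction_by_stage(m)) == 1


class TestDiscountedMoments:
    def test_zero_rewards(self):
        Pe = np.array([[1.0]])
        R = mcwr.RewardMoments([np.zeros((1, 1))] * 3, absorbing=False)
        m = mcwr.discounted_moments(Pe, R, 0.9, k=3)
        assert all(m[j][0] == 0 for j in (1, 2, 3))

    def test_single_ergodic_state_geometric_series(self):
        Pe = np.array([[1.0]])
        R = mcwr.RewardMoments([np.ones((1, 1))] * 3, absorbing=False)
        m = mcwr.discounted_moments(Pe, R, 0.9, k=3, tol=1e-13)
        assert abs(m[1][0] - 10.0) < 1e-10

    def test_absorbing_limit_recovers_undiscounted(self, stage_u):
        P = mcwr.build_absorbing_chain(stage_u)
        R = mcwr.poisson_rewards([0, 0, 0, 0, 0, 5.0], k=2)
        plain = mcwr.accumulate_moments(P, R, k=2, tol=1e-12)
        disc = mcwr.discounted_moments(P, R, 1 - 1e-6, k=2, tol=1e-12,
                                       drop_absorbing=True)
        assert np.allclose(disc[1], plain[1], rtol=1e-3)

    def test_unit_discount_on_ergodic_chain_rejected(self):
        Pe = np.array([[1.0]])
        R = mcwr.RewardMoments([np.ones((1, 1))], absorbing=False)
        with pytest.raises(ValueError, match="ergodic"):
            mcwr.discounted_moments(Pe, R, 1.0, k=1)


class TestCvSkewRatio:
    def test_small_p_limit(self):
        assert abs(mcwr.bernoulli_cv_skew_ratio(0.01) - 0.5) < 0.05

    def test_interior_value_finite_positive(self):
        r = mcwr.bernoulli_cv_skew_ratio(0.25)
        assert 0 < r < 1

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError):
            mcwr.bernoulli_cv_skew_ratio(p)

    def test_matches_high_survival_bernoulli_recursion(self):
        # the recursion on a high-survival chain with Bernoulli(0.01)
        # rewards should reproduce the closed-form ratio approximately
        P = mcwr.build_absorbing_chain(np.array([[0.999]]))
        R = mcwr.bernoulli_rewards([0.01], k=3)
        st = mcwr.lifetime_statistics(
            mcwr.accumulate_moments(P, R, k=3, tol=1e-13)).iloc[0]
        assert abs(st["cv"] / st["skew"] - mcwr.bernoulli_cv_skew_ratio(0.01)) < 0.05
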