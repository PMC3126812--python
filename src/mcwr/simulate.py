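"""Monte-Carlo simulation of individual life trajectories with rewards.

This module is the package's independent check on the analytic moment
recursions: it follows individuals step by step through an absorbing chain,
draws a random reward on every transition from the same distributions whose
moments feed the recursions, and summarises the empirical moments of the
accumulated lifetime totals with standard errors.

For time-varying models, :func:`simulate_lifetimes_env` tracks the stage and
the environment separately (demographic transition and reward first, then
the environmental move), deliberately bypassing the vec-permutation algebra
so it can serve as an independent oracle for the joint-chain construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environments import EnvironmentModel

__all__ = [
    "RewardSampler",
    "SimulationResult",
    "simulate_lifetimes",
    "simulate_lifetimes_env",
    "empirical_distribution_summary",
]

_MODELS = ("fixed", "poisson", "bernoulli", "empirical")


@dataclass
class RewardSampler:
    """Per-transition reward distribution specification.

    ``model`` is one of fixed / poisson / bernoulli / empirical.  For the
    parametric models ``params`` is the full (s+1) x (s+1) matrix of
    per-transition parameters (value, mean, or success probability), in the
    same orientation as the chain, with a zero absorbing-source column; a
    length-s stage vector is broadcast with
    :func:`mcwr.rewards.expand_to_transition_matrix`.  For the empirical
    model ``samples`` maps source stages to observed individual outputs,
    resampled with replacement (destination-independent; transitions into
    death draw the source-stage sample only when ``reward_on_death``).
    """

    model: str
    params: np.ndarray | None = field(default=None, repr=False)
    samples: dict | list | None = field(default=None, repr=False)
    reward_on_death: bool = True

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown reward model {self.model!r}")
        if self.model == "empirical":
            if self.samples is None:
                raise ValueError("empirical sampler needs per-stage samples")
            if not isinstance(self.samples, dict):
                self.samples = {j: np.asarray(o, dtype=float)
                                for j, o in enumerate(self.samples)}
            else:
                self.samples = {j: np.asarray(o, dtype=float)
                                for j, o in self.samples.items()}
            for j, o in self.samples.items():
                if o.size == 0:
                    raise ValueError(f"no observations for stage {j + 1}")
        elif self.params is None:
            raise ValueError(f"{self.model} sampler needs a parameter matrix")

    def prepared(self, n_states: int) -> np.ndarray | None:
        if self.model == "empirical":
            return None
        par = np.asarray(self.params, dtype=float)
        if par.ndim == 1:
            from .rewards import expand_to_transition_matrix
            par = expand_to_transition_matrix(
                par, reward_on_death=self.reward_on_death)
        if par.shape != (n_states, n_states):
            raise ValueError(
                f"parameter matrix {par.shape} does not match chain {n_states}")
        return par

    def draw(self, rng: np.random.Generator, par: np.ndarray | None,
             src: np.ndarray, dst: np.ndarray, absorbing: int) -> np.ndarray:
        if self.model == "fixed":
            return par[dst, src]
        if self.model == "poisson":
            return rng.poisson(par[dst, src]).astype(float)
        if self.model == "bernoulli":
            return (rng.random(src.size) < par[dst, src]).astype(float)
        out = np.zeros(src.size)
        live = np.ones(src.size, dtype=bool)
        if not self.reward_on_death:
            live = dst != absorbing
        for j, obs in self.samples.items():
            take = live & (src == j)
            if take.any():
                out[take] = rng.choice(obs, size=int(take.sum()), replace=True)
        return out


@dataclass
class SimulationResult:
    """Replicate lifetime totals with empirical moments and standard errors."""

    totals: np.ndarray = field(repr=False)
    start_state: int = 0
    seed: int | None = None
    order: int = 3

    @property
    def n(self) -> int:
        return self.totals.size

    def raw_moment(self, m: int) -> float:
        return float(np.mean(self.totals ** m))

    def raw_moment_se(self, m: int) -> float:
        return float(np.std(self.totals ** m, ddof=1) / np.sqrt(self.n))

    @property
    def raw_moments(self) -> np.ndarray:
        return np.array([self.raw_moment(m) for m in range(1, self.order + 1)])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([self.raw_moment_se(m) for m in range(1, self.order + 1)])


def _check_absorbing_chain(P: np.ndarray) -> int:
    n = P.shape[0]
    if P.ndim != 2 or P.shape[1] != n:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("P must be column-stochastic")
    last = np.zeros(n)
    last[-1] = 1.0
    if not np.allclose(P[:, -1], last):
        raise ValueError(
            "chain is not absorbing in its last state; for ergodic chains "
            "use the discounted moment engine, not simulation")
    return n


def simulate_lifetimes(P, sampler: RewardSampler, start_state: int = 0,
                       n: int = 10 ** 5, seed=None,
                       max_steps: int = 10 ** 6, order: int = 3) -> SimulationResult:
    """Simulate n independent lifetimes on an absorbing chain.

    Each replicate starts in ``start_state`` (0-based transient index),
    repeatedly draws a destination from the chain columns and a reward from
    the sampler until absorbed in the final state; returns the accumulated
    totals.  Fully reproducible given ``seed``.
    """
    P = np.asarray(P, dtype=float)
    n_states = _check_absorbing_chain(P)
    absorbing = n_states - 1
    if not 0 <= start_state < absorbing:
        raise ValueError(f"start_state {start_state} is not a transient state")
    rng = np.random.default_rng(seed)
    par = sampler.prepared(n_states)
    cdf = np.cumsum(P, axis=0).T  # row j = cdf of destinations from state j
    state = np.full(n, start_state, dtype=np.int64)
    totals = np.zeros(n)
    active = np.arange(n)
    for _ in range(max_steps):
        if active.size == 0:
            return SimulationResult(totals=totals, start_state=start_state,
                                    seed=seed, order=order)
        src = state[active]
        u = rng.random(active.size)
        dst = (cdf[src] < u[:, None]).sum(axis=1).astype(np.int64)
        totals[active] += sampler.draw(rng, par, src, dst, absorbing)
        state[active] = dst
        active = active[dst != absorbing]
    raise RuntimeError(
        f"{active.size} individuals still alive after {max_steps} steps; "
        "the chain is nearly non-absorbing")


def simulate_lifetimes_env(U_list, env: EnvironmentModel, samplers,
                           start_stage: int = 0, start_env: int = 0,
                           n: int = 10 ** 5, seed=None,
                           max_steps: int = 10 ** 6,
                           order: int = 3) -> SimulationResult:
    """Environment-aware lifetime simulation (independent of the joint-chain
    algebra): demographic transition and reward under the current
    environment's matrices, then the environment advances.

    ``samplers`` holds one RewardSampler per environment, each specified on
    the single-environment (s+1)-state chain; a single sampler is recycled.
    """
    q = env.q
    if isinstance(U_list, np.ndarray) and U_list.ndim == 2:
        U_list = [U_list] * q
    if isinstance(samplers, RewardSampler):
        samplers = [samplers] * q
    if len(U_list) != q or len(samplers) != q:
        raise ValueError("need one transient matrix and one sampler per environment")
    s = np.asarray(U_list[0]).shape[0]
    rng = np.random.default_rng(seed)
    # per-environment absorbing chains and prepared parameters
    from .chains import build_absorbing_chain
    chains = [build_absorbing_chain(U) for U in U_list]
    cdfs = [np.cumsum(Pe, axis=0).T for Pe in chains]
    pars = [smp.prepared(s + 1) for smp in samplers]
    env_cdf = np.cumsum(env.D, axis=0).T
    stage = np.full(n, start_stage, dtype=np.int64)
    envst = np.full(n, start_env, dtype=np.int64)
    totals = np.zeros(n)
    active = np.arange(n)
    for _ in range(max_steps):
        if active.size == 0:
            return SimulationResult(totals=totals,
                                    start_state=start_stage * q + start_env,
                                    seed=seed, order=order)
        src = stage[active]
        cur_env = envst[active]
        dst = np.empty(active.size, dtype=np.int64)
        rew = np.empty(active.size)
        u = rng.random(active.size)
        for e in range(q):
            here = cur_env == e
            if not here.any():
                continue
            d = (cdfs[e][src[here]] < u[here, None]).sum(axis=1).astype(np.int64)
            dst[here] = d
            rew[here] = samplers[e].draw(rng, pars[e], src[here], d, s)
        totals[active] += rew
        # environment moves after the demographic transition
        ue = rng.random(active.size)
        envst[active] = (env_cdf[cur_env] < ue[:, None]).sum(axis=1).astype(np.int64)
        stage[active] = dst
        active = active[dst != s]
    raise RuntimeError(
        f"{active.size} individuals still alive after {max_steps} steps")


def empirical_distribution_summary(result: SimulationResult, bins: int = 30):
    """Plug-in lifetime statistics and a histogram from simulated totals."""
    import pandas as pd

    x = result.totals
    if x.size < 2:
        raise ValueError("need at least 2 replicates for a variance")
    mean = float(np.mean(x))
    var = float(np.var(x))
    sd = float(np.sqrt(var))
    cv = sd / mean if mean > 0 else float("nan")
    skew = float(np.mean((x - mean) ** 3) / sd ** 3) if sd > 0 else float("nan")
    stats = pd.Series({"n": float(x.size), "mean": mean, "var": var,
                       "sd": sd, "cv": cv, "skew": skew})
    counts, edges = np.histogram(x, bins=bins)
    return stats, (counts, edges)
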