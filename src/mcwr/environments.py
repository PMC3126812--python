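"""Joint stage-by-environment chains for time-varying demography.

The environment moves among q discrete states (seasons, years since fire,
...) with its own column-stochastic transition matrix D; each state e has
its own transient matrix U_e and reward moments.  Within one projection
step an individual first makes its demographic transition (collecting the
reward of the environment it was in), and then the environment advances —
rewards ride on the demographic transition only.

Joint states are ordered stage-major / environment-fastest: position
``i * q + e`` is (stage i, environment e), so the first q entries of any
joint vector refer to stage 1 across the q environments.  With the
vec-permutation matrix K = K_{s,q} translating between this ordering and
the environment-major ordering in which blockdiag(U_1..U_q) acts, the
transient part of the joint chain is

    T = (I_s (x) D) . K . blockdiag(U_1..U_q) . K'

Death is pooled into a single absorbing state appended after the s*q joint
transient states: remaining rewards after death are zero in every
environment, so pooling changes no moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chains import validate_transient
from .moments import MomentVectors
from .rewards import RewardMoments

__all__ = [
    "EnvironmentModel",
    "JointChain",
    "vec_permutation_matrix",
    "periodic_environment",
    "sequential_environment",
    "stochastic_environment",
    "fire_environment",
    "stationary_distribution",
    "build_joint_chain",
    "build_joint_rewards",
    "average_over_stationary",
    "joint_labels",
]

_TOL = 1e-12


@dataclass
class EnvironmentModel:
    """q-state environment driver with column-stochastic transition matrix D."""

    q: int
    kind: str  # periodic | sequential | stochastic
    D: np.ndarray = field(repr=False)

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (self.q, self.q):
            raise ValueError(f"D must be {self.q}x{self.q}")
        if np.any(D < -_TOL) or not np.allclose(D.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("environment matrix D must be column-stochastic")
        self.D = D


@dataclass
class JointChain:
    """Assembled stage-by-environment absorbing chain and its factors."""

    P: np.ndarray = field(repr=False)  # (s q + 1) square, column-stochastic
    s: int = 0
    q: int = 0
    U_blocks: list = field(default_factory=list, repr=False)
    env: EnvironmentModel | None = None
    K: np.ndarray | None = field(default=None, repr=False)


def vec_permutation_matrix(s: int, q: int) -> np.ndarray:
    """Permutation K_{s,q} with K vec(X) = vec(X') for any s x q matrix X.

    Maps the environment-major ordering (all stages of environment 1, then
    environment 2, ...) to the stage-major ordering used for joint vectors.
    """
    if s < 1 or q < 1:
        raise ValueError("dimensions must be positive")
    K = np.zeros((s * q, s * q))
    for i in range(s):
        for j in range(q):
            # env-major position of (stage i, env j) -> stage-major position
            K[i * q + j, j * s + i] = 1.0
    return K


def periodic_environment(q: int) -> EnvironmentModel:
    """Deterministic seasonal cycle 1 -> 2 -> ... -> q -> 1 (circulant D)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    D = np.zeros((q, q))
    for e in range(q):
        D[(e + 1) % q, e] = 1.0
    return EnvironmentModel(q=q, kind="periodic", D=D)


def sequential_environment(q: int) -> EnvironmentModel:
    """Deterministic aperiodic sequence 1 -> 2 -> ... -> q, with the final
    state self-looping to provide an end state for the sequence."""
    if q < 1:
        raise ValueError("q must be >= 1")
    D = np.zeros((q, q))
    for e in range(q - 1):
        D[e + 1, e] = 1.0
    D[q - 1, q - 1] = 1.0
    return EnvironmentModel(q=q, kind="sequential", D=D)


def stochastic_environment(D) -> EnvironmentModel:
    D = np.asarray(D, dtype=float)
    return EnvironmentModel(q=D.shape[0], kind="stochastic", D=D)


def fire_environment(f: float) -> EnvironmentModel:
    """Four-state fire-recency chain: state 1 = year of fire, states 2-3 =
    one / two years post-fire, state 4 = three or more years post-fire.

    Each year a fire occurs with probability f (returning the environment to
    state 1); otherwise the time-since-fire clock advances, with state 4
    self-looping.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("fire frequency must lie in [0, 1]")
    D = np.zeros((4, 4))
    D[0, :] = f
    D[1, 0] = 1.0 - f
    D[2, 1] = 1.0 - f
    D[3, 2] = 1.0 - f
    D[3, 3] = 1.0 - f
    return EnvironmentModel(q=4, kind="stochastic", D=D)


def stationary_distribution(env: EnvironmentModel, tol: float = 1e-10) -> np.ndarray:
    """Stationary probabilities pi with D pi = pi, pi >= 0, sum pi = 1.

    Raises if the unit eigenvalue is not simple (reducible environment with
    no unique stationary distribution).
    """
    D = env.D
    w, V = np.linalg.eig(D)
    unit = np.nonzero(np.abs(w - 1.0) < 1e-8)[0]
    if unit.size != 1:
        raise ValueError(
            f"environment chain has {unit.size} unit eigenvalues; "
            "no unique stationary distribution (reducible chain)")
    v = np.real(V[:, unit[0]])
    pi = v / v.sum()
    if np.any(pi < -tol):
        raise ValueError("stationary vector has negative entries")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def build_joint_chain(U_list, env: EnvironmentModel) -> JointChain:
    """Assemble the joint stage-by-environment absorbing chain.

    ``U_list`` gives one s x s transient matrix per environmental state (a
    single matrix is recycled across states).  The joint transient block is
    (I_s (x) D) K blockdiag(U_e) K' on stage-major ordering, and a pooled
    absorbing death state is appended.
    """
    if isinstance(U_list, np.ndarray) and U_list.ndim == 2:
        U_list = [U_list] * env.q
    U_list = [validate_transient(U) for U in U_list]
    if len(U_list) != env.q:
        raise ValueError(f"need {env.q} transient matrices, got {len(U_list)}")
    s = U_list[0].shape[0]
    for U in U_list:
        if U.shape != (s, s):
            raise ValueError("all transient matrices must share one dimension")
    q = env.q
    K = vec_permutation_matrix(s, q)
    Ublk = np.zeros((s * q, s * q))
    for e, U in enumerate(U_list):
        Ublk[e * s:(e + 1) * s, e * s:(e + 1) * s] = U
    Dblk = np.kron(np.eye(s), env.D)
    T = Dblk @ K @ Ublk @ K.T
    n = s * q
    P = np.zeros((n + 1, n + 1))
    P[:n, :n] = T
    P[n, :n] = 1.0 - T.sum(axis=0)
    P[n, n] = 1.0
    return JointChain(P=P, s=s, q=q, U_blocks=U_list, env=env, K=K)


def build_joint_rewards(R_list, s: int, q: int) -> RewardMoments:
    """Joint reward moment matrices aligned with the joint chain ordering.

    ``R_list`` holds one RewardMoments per environment, each over the
    single-environment (s+1)-state chain (a single set is recycled).  The
    reward for joint transition (i, e) -> (i', e') is the stage transition
    reward of environment e — the environment the individual occupied when
    it made the demographic transition — independent of e'.  Transitions
    into the pooled death state carry the per-environment death-row reward.
    """
    if isinstance(R_list, RewardMoments):
        R_list = [R_list] * q
    if len(R_list) != q:
        raise ValueError(f"need {q} reward sets, got {len(R_list)}")
    k = R_list[0].order
    for R in R_list:
        if R.order != k:
            raise ValueError("all environments must share one moment order k")
        if R.s != s:
            raise ValueError("reward dimensions do not match s")
    n = s * q
    mats = []
    for m in range(1, k + 1):
        Rm = np.zeros((n + 1, n + 1))
        for e in range(q):
            block = R_list[e][m]  # (s+1) x (s+1), source env e
            src = np.arange(s) * q + e
            for i_dst in range(s):
                dst = i_dst * q + np.arange(q)
                # destination environment does not change the reward
                Rm[np.ix_(dst, src)] = np.tile(block[i_dst, :s], (q, 1))
            Rm[n, src] = block[s, :s]
        mats.append(Rm)
    return RewardMoments(mats)


def joint_labels(s: int, q: int) -> list[str]:
    return [f"stage_{i + 1}|env_{e + 1}" for i in range(s) for e in range(q)]


def average_over_stationary(m: MomentVectors, pi, s: int, q: int,
                            tol: float = 1e-8) -> MomentVectors:
    """Average joint raw moments over the stationary distribution of the
    starting environment, giving moments by starting stage alone.

    Raw moments are averaged (a pi-mixture of starting conditions), and any
    derived statistic is computed afterwards from the averaged moments.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (q,):
        raise ValueError(f"pi must have length {q}")
    if abs(pi.sum() - 1.0) > tol:
        raise ValueError(f"stationary weights sum to {pi.sum():.12g}, not 1")
    out = []
    for j in range(1, m.order + 1):
        v = m[j]
        if v.size != s * q:
            raise ValueError("moment vectors do not match s*q joint states")
        out.append(v.reshape(s, q) @ pi)
    return MomentVectors(rho=out, iterations=m.iterations, residual=m.residual,
                         labels=[f"stage_{i + 1}" for i in range(s)])
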