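"""Matrices of raw moments of transition-specific rewards.

A reward here is the (possibly random) reproductive output collected when an
individual makes one transition of the absorbing chain.  The moment engine
needs, for each moment order m, an (s+1) x (s+1) matrix whose (i, j) entry is
E[r^m] for the transition from source stage j to destination stage i.  The
dead collect nothing, so the column of the absorbing state is always zero.

In most models the reward depends only on the source stage (reproduction
during the interval is independent of where the individual ends up), so the
builders accept a length-s vector of stage parameters and broadcast it over
destinations.  Destination-dependent full matrices are accepted unchanged,
which covers life cycles where reproduction rides on the transition into a
reproductive state.

The ``reward_on_death`` switch controls whether the stage-j reward is also
collected on the transition into death (reproduction before death within the
interval, the permissive default) or zeroed on that row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "RewardMoments",
    "poisson_raw_moments",
    "poisson_rewards",
    "bernoulli_rewards",
    "fixed_rewards",
    "empirical_rewards",
    "unit_longevity_rewards",
    "expand_to_transition_matrix",
]


@dataclass
class RewardMoments:
    """Raw-moment matrices R_1..R_k of transition-specific rewards.

    ``matrices[m-1]`` is the (s+1) x (s+1) matrix of mth raw moments;
    ``s`` is the number of transient stages.
    """

    matrices: list = field(repr=False)
    s: int = 0
    absorbing: bool = True

    def __post_init__(self):
        mats = [np.asarray(R, dtype=float) for R in self.matrices]
        if not mats:
            raise ValueError("at least one moment matrix is required")
        n = mats[0].shape[0]
        for R in mats:
            if R.shape != (n, n):
                raise ValueError("all moment matrices must share one shape")
            if np.any(~np.isfinite(R)) or np.any(R < 0):
                raise ValueError("reward moments must be finite and nonnegative")
            if self.absorbing and np.any(R[:, -1] != 0):
                raise ValueError("absorbing-source column of rewards must be zero")
        self.matrices = mats
        self.s = n - 1 if self.absorbing else n

    @property
    def order(self) -> int:
        return len(self.matrices)

    def __getitem__(self, m: int) -> np.ndarray:
        """1-based access: rewards[m] is the matrix of mth raw moments."""
        if not 1 <= m <= self.order:
            raise IndexError(f"moment order {m} outside 1..{self.order}")
        return self.matrices[m - 1]


def expand_to_transition_matrix(stage_values, s: int | None = None,
                                reward_on_death: bool = True) -> np.ndarray:
    """Broadcast per-source-stage values to a full (s+1) x (s+1) matrix.

    A length-s vector is replicated down every destination row (death row
    included unless ``reward_on_death`` is false); a full square matrix of
    size s or s+1 passes through (padded/row-masked as needed).  The
    absorbing-source column is always zero.
    """
    V = np.asarray(stage_values, dtype=float)
    if V.ndim == 1:
        if s is None:
            s = V.size
        if V.size != s:
            raise ValueError(f"expected a length-{s} stage vector, got {V.size}")
        M = np.zeros((s + 1, s + 1))
        M[:, :s] = np.tile(V, (s + 1, 1))
    elif V.ndim == 2 and V.shape[0] == V.shape[1]:
        n = V.shape[0]
        if s is not None and n not in (s, s + 1):
            raise ValueError(f"matrix of size {n} incompatible with s={s}")
        if s is None or n == s + 1:
            # already includes the absorbing row/column
            M = V.copy()
        else:
            # destination-dependent rewards among living stages; the death
            # row carries the source-stage value only when the reward is in
            # fact source-determined, otherwise a destination-specific
            # reward cannot ride on the transition into death
            M = np.zeros((s + 1, s + 1))
            M[:s, :s] = V
            if np.allclose(V.min(axis=0), V.max(axis=0)):
                M[s, :s] = V[0, :]
    else:
        raise ValueError("stage_values must be a vector or a square matrix")
    if not reward_on_death:
        M[-1, :] = 0.0
    M[:, -1] = 0.0
    return M


def _build_from_stage_moments(moment_fn, params, k: int,
                              reward_on_death: bool) -> RewardMoments:
    """Assemble R_1..R_k from a per-parameter raw-moment function."""
    par = np.asarray(params, dtype=float)
    mats = []
    for m in range(1, k + 1):
        mom = moment_fn(par, m)
        mats.append(expand_to_transition_matrix(
            mom, s=None if par.ndim == 1 else par.shape[0],
            reward_on_death=reward_on_death))
    return RewardMoments(mats)


def poisson_raw_moments(lam, m: int):
    """mth raw moment of a Poisson(lam) variable (Touchard recurrence).

    mu_0 = 1 and mu_{j+1} = lam * sum_i C(j, i) mu_i, which is numerically
    robust for any order; mu_1 = lam, mu_2 = lam + lam^2,
    mu_3 = lam + 3 lam^2 + lam^3.
    """
    lam = np.asarray(lam, dtype=float)
    mus = [np.ones_like(lam)]
    for j in range(m):
        nxt = lam * sum(comb(j, i) * mus[i] for i in range(j + 1))
        mus.append(nxt)
    return mus[m]


def poisson_rewards(mean_rewards, k: int = 3,
                    reward_on_death: bool = True) -> RewardMoments:
    """Reward moments when stage-specific reproduction is Poisson distributed."""
    par = np.asarray(mean_rewards, dtype=float)
    if np.any(par < 0):
        raise ValueError("Poisson means must be nonnegative")
    if k < 1:
        raise ValueError("order k must be >= 1")
    return _build_from_stage_moments(poisson_raw_moments, par, k, reward_on_death)


def bernoulli_rewards(p, k: int = 3, reward_on_death: bool = True) -> RewardMoments:
    """Reward moments for at-most-one offspring per interval: E[r^m] = p."""
    par = np.asarray(p, dtype=float)
    if np.any(par < 0) or np.any(par > 1):
        raise ValueError("Bernoulli probabilities must lie in [0, 1]")
    if k < 1:
        raise ValueError("order k must be >= 1")
    return _build_from_stage_moments(lambda q, m: q.copy(), par, k, reward_on_death)


def fixed_rewards(values, k: int = 3, reward_on_death: bool = True) -> RewardMoments:
    """Degenerate rewards: every individual in stage j produces exactly m_j,
    so E[r^m] = m_j^m."""
    par = np.asarray(values, dtype=float)
    if np.any(par < 0):
        raise ValueError("fixed rewards must be nonnegative")
    if k < 1:
        raise ValueError("order k must be >= 1")
    return _build_from_stage_moments(lambda q, m: q ** m, par, k, reward_on_death)


def unit_longevity_rewards(s: int, k: int = 3) -> RewardMoments:
    """Unit reward for each time step spent in any living stage.

    The accumulated lifetime reward is then longevity, so the moment engine
    returns the moments of lifespan; these can be cross-checked against the
    fundamental matrix.
    """
    return fixed_rewards(np.ones(s), k=k, reward_on_death=True)


def empirical_rewards(samples, k: int = 3, s: int | None = None,
                      reward_on_death: bool = True) -> RewardMoments:
    """Reward moments computed directly from per-stage individual data.

    ``samples`` maps each stage (0-based index into the transient stages) to
    a sequence of observed individual reproductive outputs over one
    projection interval; a list of per-stage sequences is also accepted.
    Stages absent from ``samples`` get zero reward (non-reproductive stage);
    a stage present but empty is an error.  E[r^m] is the plain mean of mth
    powers, matching the raw-moment definition.
    """
    if isinstance(samples, dict):
        items = samples
        if s is None:
            s = max(items) + 1
    else:
        items = {j: obs for j, obs in enumerate(samples)}
        if s is None:
            s = len(items)
    mats = []
    stage_moms = np.zeros((k, s))
    for j, obs in items.items():
        if not 0 <= j < s:
            raise ValueError(f"stage index {j} outside 0..{s - 1}")
        x = np.asarray(obs, dtype=float)
        if x.size == 0:
            raise ValueError(f"no reward observations for stage {j + 1}")
        if np.any(x < 0):
            raise ValueError(f"negative reward observed in stage {j + 1}")
        for m in range(1, k + 1):
            stage_moms[m - 1, j] = np.mean(x ** m)
    for m in range(1, k + 1):
        mats.append(expand_to_transition_matrix(stage_moms[m - 1],
                                                reward_on_death=reward_on_death))
    return RewardMoments(mats)
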