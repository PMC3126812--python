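"""Backward recursions for the moments of accumulated lifetime reward.

An individual in stage j with t steps to go makes a transition j -> i with
probability ``P[i, j]``, collects a random reward r_ij there, and then holds
whatever future reward rho(t-1) the destination promises.  Taking
expectations of the binomial expansion of (r + rho)^m and summing over
destinations yields, in matrix form, the coupled recursions

    rho_m(t+1) = sum_{j=0}^{m-1} C(m, j) (P o R_{m-j})' rho_j(t) + P' rho_m(t)

with rho_0 = 1 and rho_m(0) = 0 (no rewards accumulate after the terminal
time).  "o" is the Hadamard product and R_m holds the mth raw moments of the
transition rewards.  For an absorbing chain with zero rewards to the dead the
iteration converges to the raw moments of *lifetime* accumulated reward as a
function of starting stage; the absorbing entry stays identically zero and is
dropped on output.

Discounted variant: if future rewards are devalued by a factor ``d`` per step
the conditional accumulation is r + d*rho, so the j-th term above picks up
d**j.  With 0 < d < 1 the iteration converges even on ergodic chains, where
undiscounted rewards would grow without bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .rewards import RewardMoments

__all__ = [
    "MomentVectors",
    "accumulate_moments",
    "discounted_moments",
    "lifetime_statistics",
    "remaining_reproduction_by_stage",
    "bernoulli_cv_skew_ratio",
]

_OVERFLOW_GUARD = 1e300


@dataclass
class MomentVectors:
    """Raw moments rho_1..rho_k of accumulated reward, by starting state.

    ``rho[m-1]`` is the length-n vector of mth raw moments over the transient
    states (absorbing entry already dropped).  ``iterations`` and
    ``residual`` record the convergence of the backward iteration.
    """

    rho: list = field(repr=False)
    iterations: int = 0
    residual: float = 0.0
    labels: list | None = None

    @property
    def order(self) -> int:
        return len(self.rho)

    def __getitem__(self, m: int) -> np.ndarray:
        if not 1 <= m <= self.order:
            raise IndexError(f"moment order {m} outside 1..{self.order}")
        return self.rho[m - 1]


def _check_inputs(P, R: RewardMoments, k: int):
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.ndim != 2 or P.shape[1] != n:
        raise ValueError("P must be square")
    if k < 1:
        raise ValueError("order k must be >= 1")
    if R.order < k:
        raise ValueError(f"reward moments of order {R.order} cannot support k={k}")
    if R.matrices[0].shape != P.shape:
        raise ValueError(
            f"reward matrices {R.matrices[0].shape} do not match P {P.shape}")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("P must be column-stochastic")
    return P, n


def _iterate(P, R: RewardMoments, k: int, tol: float, max_iter: int,
             discount: float = 1.0):
    """Shared fixed-point loop; discount=1 is the plain absorbing case."""
    P, n = _check_inputs(P, R, k)
    PT = P.T.copy()
    # M_j = (P o R_j)^T; row j of the transposed product maps source stages
    MT = [None] + [(P * R[j]).T for j in range(1, k + 1)]
    ones = np.ones(n)
    rho = [np.zeros(n) for _ in range(k)]
    binoms = [[comb(m, j) for j in range(m)] for m in range(k + 1)]
    for it in range(1, max_iter + 1):
        resid = 0.0
        prev = [v for v in rho]
        new = []
        for m in range(1, k + 1):
            acc = MT[m] @ ones  # j = 0 term, rho_0 = 1
            for j in range(1, m):
                acc = acc + binoms[m][j] * (discount ** j) * (MT[m - j] @ prev[j - 1])
            acc = acc + (discount ** m) * (PT @ prev[m - 1])
            new.append(acc)
            resid = max(resid, float(np.max(np.abs(acc - prev[m - 1]), initial=0.0)))
        rho = new
        if any(np.any(np.abs(v) > _OVERFLOW_GUARD) for v in rho):
            raise FloatingPointError(
                "accumulated moments exceed 1e300; reduce the order or add a discount")
        if resid < tol:
            return rho, it, resid
    raise RuntimeError(
        f"moment recursion did not converge in {max_iter} iterations "
        f"(residual {resid:.3g}); the chain may be nearly non-absorbing")


def accumulate_moments(P, R: RewardMoments, k: int = 3, tol: float = 1e-10,
                       max_iter: int = 10 ** 6,
                       drop_absorbing: bool = True) -> MomentVectors:
    """Iterate the backward recursions to the lifetime-reward moments.

    ``P`` is the (s+1) x (s+1) column-stochastic absorbing chain and ``R``
    the matching reward moment matrices.  Orders are updated jointly in a
    single sweep per backward step, lower orders feeding higher ones.  The
    result holds rho_1..rho_k over the s transient stages.
    """
    rho, it, resid = _iterate(P, R, k, tol, max_iter, discount=1.0)
    if drop_absorbing:
        for v in rho:
            if abs(v[-1]) > 100 * tol:
                raise RuntimeError(
                    f"absorbing-state moment {v[-1]:.3g} is not zero; "
                    "reward matrices are inconsistent with the chain")
        rho = [v[:-1] for v in rho]
    return MomentVectors(rho=rho, iterations=it, residual=resid)


def discounted_moments(P, R: RewardMoments, discount: float, k: int = 3,
                       tol: float = 1e-10, max_iter: int = 10 ** 6,
                       drop_absorbing: bool = False) -> MomentVectors:
    """Moments of discounted accumulated reward.

    For ergodic chains a strict discount (0 < d < 1) is required for the
    accumulation to converge; absorbing chains also admit d = 1, recovering
    ``accumulate_moments``.
    """
    P = np.asarray(P, dtype=float)
    if not 0.0 < discount <= 1.0:
        raise ValueError("discount must lie in (0, 1]")
    if discount == 1.0:
        from .chains import spectral_radius
        if spectral_radius(P) >= 1 and not _has_absorbing(P, R):
            raise ValueError(
                "discount = 1 on an ergodic chain: rewards accumulate forever")
    rho, it, resid = _iterate(P, R, k, tol, max_iter, discount=discount)
    if drop_absorbing:
        rho = [v[:-1] for v in rho]
    return MomentVectors(rho=rho, iterations=it, residual=resid)


def _has_absorbing(P: np.ndarray, R: RewardMoments) -> bool:
    n = P.shape[0]
    e_last = np.zeros(n)
    e_last[-1] = 1.0
    return bool(np.allclose(P[:, -1], e_last) and np.all(R[1][:, -1] == 0))


def lifetime_statistics(m: MomentVectors, tol: float = 1e-8,
                        labels=None) -> pd.DataFrame:
    """Derived statistics per starting state from the raw moment vectors.

    variance = rho2 - rho1^2, sd = sqrt(variance), cv = sd / rho1 and
    skewness = (rho3 - 3 rho1 rho2 + 2 rho1^3) / sd^3.  Zero-variance or
    zero-mean states get NaN for the undefined ratios rather than an error;
    a variance below -tol signals numerical inconsistency and raises.
    """
    r1 = m[1]
    data = {"rho1": r1, "mean": r1}
    if m.order >= 2:
        var = m[2] - r1 ** 2
        if np.any(var < -tol):
            raise FloatingPointError(
                f"negative variance {var.min():.3g}: inconsistent moments")
        var = np.clip(var, 0.0, None)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(r1 > 0, sd / np.where(r1 > 0, r1, 1.0), np.nan)
        data.update(rho2=m[2], var=var, sd=sd, cv=cv)
    if m.order >= 3:
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(sd > 0,
                            (m[3] - 3 * r1 * m[2] + 2 * r1 ** 3)
                            / np.where(sd > 0, sd, 1.0) ** 3,
                            np.nan)
        data.update(rho3=m[3], skew=skew)
    for j in range(4, m.order + 1):
        data[f"rho{j}"] = m[j]
    idx = labels if labels is not None else m.labels
    if idx is None:
        idx = [f"stage_{i + 1}" for i in range(r1.size)]
    cols = [c for c in ("mean", "var", "sd", "cv", "skew") if c in data]
    cols += [c for c in data if c.startswith("rho")]
    return pd.DataFrame(data, index=pd.Index(idx, name="state"))[cols]


def remaining_reproduction_by_stage(m: MomentVectors, labels=None) -> pd.DataFrame:
    """Statistics of *remaining* lifetime reward for an individual currently
    in each stage — the same vectors read along the stage axis."""
    return lifetime_statistics(m, labels=labels)


def bernoulli_cv_skew_ratio(p: float) -> float:
    """CV-to-skewness ratio of lifetime offspring counts under per-step
    Bernoulli(p) reproduction sustained over a long, high-survival life.

    The lifetime count is then geometrically distributed, for which
    CV / skewness = 1 / (2 - p): approximately one half when the per-step
    probability of reproducing is small.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    return 1.0 / (2.0 - p)
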