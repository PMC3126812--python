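"""Synthetic demographic inputs: Leslie and stage-structured matrices,
reward schedules, and overdispersed cohort samples.

The named 6-stage perennial-plant matrices shipped here are *synthetic*
stand-ins constructed to have the documented life-cycle structure of the
published case-study species (germinant/seedling progression, movement in
both directions among the larger size classes, reproduction confined to the
flowering stages); they are not transcriptions of any published matrix and
exercise the machinery structurally, not numerically.
"""

from __future__ import annotations

import numpy as np

from .chains import validate_transient
from .environments import fire_environment

__all__ = [
    "leslie_from_schedule",
    "random_stage_model",
    "synthetic_cohort",
    "paper_fixture",
    "FIXTURE_NAMES",
]


def leslie_from_schedule(survival, fertility):
    """Leslie matrices (U, F) from age schedules of survival p_x and
    fertility f_x.

    U carries p_x on the subdiagonal (the last age class dies with
    probability 1) and F carries the fertilities in its first row.  Age
    self-loops are not part of a Leslie model; use a stage model for those.
    """
    p = np.asarray(survival, dtype=float)
    f = np.asarray(fertility, dtype=float)
    if p.ndim != 1 or p.shape != f.shape:
        raise ValueError("survival and fertility must be equal-length vectors")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("survival probabilities must lie in [0, 1]")
    if np.any(f < 0):
        raise ValueError("fertilities must be nonnegative")
    w = p.size
    if w < 2:
        raise ValueError("a Leslie model needs at least 2 age classes "
                         "(a single age class would need a self-loop)")
    U = np.zeros((w, w))
    U[np.arange(1, w), np.arange(w - 1)] = p[:-1]
    F = np.zeros((w, w))
    F[0, :] = f
    return validate_transient(U), F


def random_stage_model(s: int, seed=None, self_loops: bool = True,
                       retrogression: bool = True,
                       max_colsum: float = 0.95) -> np.ndarray:
    """Random column-substochastic stage matrix with optional stasis and
    retrogression structure; spectral radius < 1 by construction."""
    if s < 2:
        raise ValueError("need at least 2 stages")
    rng = np.random.default_rng(seed)
    U = rng.random((s, s))
    if not self_loops:
        np.fill_diagonal(U, 0.0)
    if not retrogression:
        U = np.tril(U)  # nothing above the diagonal: no shrinking back
    colsum = U.sum(axis=0)
    target = rng.uniform(0.3, max_colsum, size=s)
    U = U * (target / np.where(colsum > 0, colsum, 1.0))
    return validate_transient(U)


def synthetic_cohort(mean_schedule, dispersion: float = 1.0,
                     n_individuals: int = 1000, seed=None) -> dict:
    """Per-stage samples of individual reproductive output with a target
    mean and index of dispersion (variance-to-mean ratio).

    dispersion = 1 draws Poisson counts; dispersion > 1 draws a
    gamma-Poisson (negative binomial) mixture, the simplest count model
    matching an arbitrary overdispersion.  Stages with zero mean yield
    all-zero samples.
    """
    mu = np.asarray(mean_schedule, dtype=float)
    if np.any(mu < 0):
        raise ValueError("means must be nonnegative")
    if dispersion < 1:
        raise ValueError("underdispersed cohorts (dispersion < 1) unsupported")
    rng = np.random.default_rng(seed)
    out = {}
    for j, m in enumerate(mu):
        if m == 0:
            out[j] = np.zeros(n_individuals)
        elif dispersion == 1:
            out[j] = rng.poisson(m, size=n_individuals).astype(float)
        else:
            theta = dispersion - 1.0          # gamma scale
            shape = m / theta                 # gamma shape: mean m, var m*theta
            lam = rng.gamma(shape, theta, size=n_individuals)
            out[j] = rng.poisson(lam).astype(float)
    return out


def _synthetic_trillium_like_u() -> np.ndarray:
    """Synthetic 6-stage forest-herb transient matrix (germinant, seedling,
    one-leaf, small, large, reproductive) with stasis and retrogression
    among stages 4-6.  Synthetic stand-in, not a published matrix."""
    U = np.array([
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
        [0.70, 0.05, 0.00, 0.00, 0.00, 0.00],
        [0.00, 0.60, 0.45, 0.05, 0.00, 0.00],
        [0.00, 0.00, 0.30, 0.50, 0.10, 0.05],
        [0.00, 0.00, 0.00, 0.30, 0.55, 0.20],
        [0.00, 0.00, 0.00, 0.05, 0.30, 0.70],
    ])
    return validate_transient(U)


def _synthetic_lomatium_like_u() -> np.ndarray:
    """Synthetic 6-stage prairie-perennial transient matrix (seedling, small
    vegetative, large vegetative, small/medium/large reproductive) with
    considerable movement among the larger classes.  Synthetic stand-in for
    a post-fire environmental state, not a published matrix."""
    U = np.array([
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
        [0.55, 0.30, 0.10, 0.05, 0.00, 0.00],
        [0.05, 0.40, 0.40, 0.15, 0.10, 0.05],
        [0.00, 0.10, 0.25, 0.35, 0.25, 0.15],
        [0.00, 0.00, 0.10, 0.25, 0.35, 0.30],
        [0.00, 0.00, 0.00, 0.10, 0.25, 0.45],
    ])
    return validate_transient(U)


FIXTURE_NAMES = ("trillium_like_u", "lomatium_like_u", "fire_env")


def paper_fixture(name: str, fire_frequency: float = 0.5):
    """Named demonstration fixtures.

    ``trillium_like_u`` and ``lomatium_like_u`` are clearly labelled
    synthetic stand-ins with the documented case-study life-cycle structure;
    ``fire_env`` is the exactly specified four-state fire-recency
    environment (parameterised by ``fire_frequency``).
    """
    if name == "trillium_like_u":
        return _synthetic_trillium_like_u()
    if name == "lomatium_like_u":
        return _synthetic_lomatium_like_u()
    if name == "fire_env":
        return fire_environment(fire_frequency).D
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
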