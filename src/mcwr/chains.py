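"""Absorbing demographic chains and classical net-reproductive-rate checks.

Conventions
-----------
All matrices are column-oriented: entry ``(i, j)`` is the probability (or
expected offspring) associated with moving *from* stage ``j`` *to* stage
``i`` over one projection interval, the standard orientation for matrix
population models.  The transient matrix ``U`` (s x s) collects survival
transitions among living stages; the implied per-stage mortality is
``1 - column sum``.  Appending death as a final absorbing state yields the
(s+1) x (s+1) column-stochastic chain ``P``::

    P = [[ U , 0 ],
         [ m', 1 ]]          m' = 1' - 1'U

Stages are reported 1-based in all user-facing output; storage is 0-based.
"""

from __future__ import annotations

import numpy as np

DEFAULT_TOL = 1e-12

__all__ = [
    "validate_transient",
    "build_absorbing_chain",
    "mortality_vector",
    "fundamental_matrix",
    "expected_longevity",
    "net_reproductive_rate",
    "r0_age_classified",
    "spectral_radius",
]


def _as_matrix(M, name: str) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {A.shape}")
    return A


def spectral_radius(M) -> float:
    """Modulus of the dominant eigenvalue (the Perron root for nonnegative M)."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(M, dtype=float)))))


def validate_transient(U, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Validate a transient (survival/transition) matrix U.

    Checks: square, entries in [0, 1], column sums <= 1 + tol, and spectral
    radius strictly below 1 so that every individual eventually dies and
    lifetime accumulations converge.

    Returns the validated array (float, copied).
    """
    A = _as_matrix(U, "U").copy()
    if np.any(~np.isfinite(A)):
        raise ValueError("U contains non-finite entries")
    if np.any(A < -tol) or np.any(A > 1 + tol):
        raise ValueError("U entries must be probabilities in [0, 1]")
    colsum = A.sum(axis=0)
    bad = np.nonzero(colsum > 1 + tol)[0]
    if bad.size:
        raise ValueError(
            f"column sums of U exceed 1 for stages {list(bad + 1)} "
            f"(max sum {colsum.max():.15g})"
        )
    rho = spectral_radius(A)
    if rho >= 1 - tol:
        raise ValueError(
            f"spectral radius of U is {rho:.15g} >= 1: the cohort never dies "
            "and lifetime rewards would not converge"
        )
    return A


def mortality_vector(U, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Per-stage death probabilities m' = 1' - 1'U."""
    A = validate_transient(U, tol)
    return np.clip(1.0 - A.sum(axis=0), 0.0, 1.0)


def build_absorbing_chain(U, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Append death as an absorbing state: (s+1) x (s+1) column-stochastic P.

    The leading s x s block is U, the last row holds the mortality
    probabilities, and the last column is the unit vector on death.
    """
    A = validate_transient(U, tol)
    s = A.shape[0]
    P = np.zeros((s + 1, s + 1))
    P[:s, :s] = A
    P[s, :s] = 1.0 - A.sum(axis=0)
    P[s, s] = 1.0
    # exact column-stochasticity, absorbing renormalisation of rounding dust
    P[s, :s] = 1.0 - P[:s, :s].sum(axis=0)
    return P


def fundamental_matrix(U, tol: float = DEFAULT_TOL) -> np.ndarray:
    """N = (I - U)^-1; entry (i, j) = expected visits to i starting from j."""
    A = validate_transient(U, tol)
    I = np.eye(A.shape[0])
    try:
        N = np.linalg.solve(I - A, I)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rho<1
        raise ValueError("I - U is singular: non-convergent life cycle") from exc
    return N


def expected_longevity(U, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Expected remaining lifetime (time steps) by starting stage: 1'N."""
    return fundamental_matrix(U, tol).sum(axis=0)


def net_reproductive_rate(U, F, tol: float = DEFAULT_TOL) -> float:
    """R0 = dominant eigenvalue of F (I - U)^-1 for a stage-classified model.

    ``F`` is the matrix of stage-specific fertilities (expected offspring per
    individual per projection interval).
    """
    A = validate_transient(U, tol)
    Fm = _as_matrix(F, "F")
    if Fm.shape != A.shape:
        raise ValueError(f"F shape {Fm.shape} does not match U shape {A.shape}")
    if np.any(Fm < 0):
        raise ValueError("F must be nonnegative")
    R = Fm @ fundamental_matrix(A, tol)
    ev = np.linalg.eigvals(R)
    r0 = ev[np.argmax(np.abs(ev))]
    return float(abs(r0))


def r0_age_classified(survival, fertility) -> float:
    """Classical age-classified net reproductive rate, sum_x l_x f_x.

    ``survival[x]`` is the probability of surviving from age class x to x+1
    and ``fertility[x]`` the expected offspring of an age-x individual, so
    survivorship to age x is l_x = prod of survival up to x (l_0 = 1).
    """
    p = np.asarray(survival, dtype=float)
    f = np.asarray(fertility, dtype=float)
    if p.shape != f.shape or p.ndim != 1:
        raise ValueError("survival and fertility must be 1-d vectors of equal length")
    l = np.concatenate([[1.0], np.cumprod(p)[:-1]])
    return float(np.sum(l * f))
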