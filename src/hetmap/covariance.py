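"""Bivariate first-order structured antedependence [SAD(1)] residual model.

The residual pair e(t) = (e1(t), e2(t)) at each observation time depends
linearly on the previous time's residuals of *both* variables plus a fresh
bivariate-normal innovation:

    e1(t) = a1 e1(t-1) + c1 e2(t-1) + eps1(t)
    e2(t) = c2 e1(t-1) + a2 e2(t-1) + eps2(t),        e(0) = 0,

with innovations eps(t) ~ N2(0, Sigma_eps), Sigma_eps time-independent with
standard deviations nu1, nu2 and correlation rho.  Writing
Phi = [[a1, c1], [c2, a2]], the covariance recursion is V(1) = Sigma_eps,
V(t) = Phi V(t-1) Phi' + Sigma_eps, and Cov(e(t), e(s)) = Phi^{t-s} V(s)
for t > s.

Because the stacked residual vector is a unit-determinant (unit lower
block-triangular) linear transform of the stacked innovations, the full
2T x 2T covariance has the closed-form log-determinant
T log(nu1^2 nu2^2 (1 - rho^2)) regardless of the lag coefficients.  No
stationarity is imposed: the process runs over a finite horizon, and the
lag coefficients used in practice may well exceed one in modulus.

Matrices are returned in the variable-major layout (x1 block, cross block,
x2 block) matching the stacked mean vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class SADParams:
    """SAD(1) parameters.

    a1, a2 : own-lag coefficients of variables 1 and 2.
    c1, c2 : cross-lag coefficients (variable 2 into 1, and 1 into 2).
    nu1, nu2 : innovation standard deviations (> 0).
    rho : innovation correlation (|rho| < 1).
    """

    a1: float
    a2: float
    c1: float
    c2: float
    nu1: float
    nu2: float
    rho: float

    def __post_init__(self):
        vals = (self.a1, self.a2, self.c1, self.c2, self.nu1, self.nu2, self.rho)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("SAD parameters must be finite")
        if self.nu1 <= 0 or self.nu2 <= 0:
            raise InvalidParameterError("innovation SDs nu1, nu2 must be > 0")
        if abs(self.rho) >= 1:
            raise InvalidParameterError("|rho| must be < 1")

    def lag_matrix(self) -> np.ndarray:
        return np.array([[self.a1, self.c1], [self.c2, self.a2]])

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a1, self.a2, self.c1, self.c2, self.nu1, self.nu2, self.rho]
        )

    @classmethod
    def from_array(cls, v) -> "SADParams":
        return cls(*(float(x) for x in np.asarray(v)))


def innovation_matrix(nu1: float, nu2: float, rho: float) -> np.ndarray:
    """2x2 innovation covariance [[nu1^2, nu1 nu2 rho], [., nu2^2]]."""
    if nu1 <= 0 or nu2 <= 0:
        raise InvalidParameterError("innovation SDs must be > 0")
    if abs(rho) >= 1:
        raise InvalidParameterError("|rho| must be < 1")
    off = nu1 * nu2 * rho
    return np.array([[nu1 * nu1, off], [off, nu2 * nu2]])


def _variable_major_permutation(T: int) -> np.ndarray:
    """Index map: variable-major position -> time-major position."""
    idx = np.empty(2 * T, dtype=np.int64)
    for v in range(2):
        for t in range(T):
            idx[v * T + t] = 2 * t + v
    return idx


def marginal_variances(psi: SADParams, T: int) -> np.ndarray:
    """Per-time 2x2 marginal covariances V(t), t = 1..T, shape (T, 2, 2)."""
    if T < 1:
        raise InvalidParameterError("T must be >= 1")
    phi = psi.lag_matrix()
    sig = innovation_matrix(psi.nu1, psi.nu2, psi.rho)
    V = np.empty((T, 2, 2))
    V[0] = sig
    for t in range(1, T):
        V[t] = phi @ V[t - 1] @ phi.T + sig
    return V


def sad1_covariance(psi: SADParams, T: int) -> np.ndarray:
    """Assemble the 2T x 2T residual covariance in variable-major layout."""
    V = marginal_variances(psi, T)
    phi = psi.lag_matrix()
    # Phi powers 0..T-1 for the cross-time blocks.
    powers = np.empty((T, 2, 2))
    powers[0] = np.eye(2)
    for k in range(1, T):
        powers[k] = phi @ powers[k - 1]
    C = np.empty((2 * T, 2 * T))
    for s in range(T):
        C[2 * s: 2 * s + 2, 2 * s: 2 * s + 2] = V[s]
        for t in range(s + 1, T):
            block = powers[t - s] @ V[s]  # Cov(e(t), e(s))
            C[2 * t: 2 * t + 2, 2 * s: 2 * s + 2] = block
            C[2 * s: 2 * s + 2, 2 * t: 2 * t + 2] = block.T
    perm = _variable_major_permutation(T)
    return C[np.ix_(perm, perm)]


def sad1_logdet(psi: SADParams, T: int) -> float:
    """Closed-form log-determinant of the 2T x 2T SAD(1) covariance."""
    if T < 1:
        raise InvalidParameterError("T must be >= 1")
    det_sig = psi.nu1**2 * psi.nu2**2 * (1.0 - psi.rho**2)
    return T * math.log(det_sig)


def simulate_residual_matrix(
    psi: SADParams, T: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n residual paths, shape (n, 2T), variable-major (vectorized)."""
    if T < 1:
        raise InvalidParameterError("T must be >= 1")
    L = np.linalg.cholesky(innovation_matrix(psi.nu1, psi.nu2, psi.rho))
    phi = psi.lag_matrix()
    eps = rng.standard_normal((T, n, 2)) @ L.T
    E = np.empty((T, n, 2))
    E[0] = eps[0]
    for t in range(1, T):
        E[t] = E[t - 1] @ phi.T + eps[t]
    # (T, n, 2) -> variable-major (n, 2T)
    return np.concatenate([E[:, :, 0].T, E[:, :, 1].T], axis=1)


def simulate_residuals(psi: SADParams, T: int, seed: int) -> np.ndarray:
    """One residual path of length 2T via the exact recursion,
    deterministic given the seed."""
    rng = np.random.default_rng(seed)
    return simulate_residual_matrix(psi, T, 1, rng)[0]
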