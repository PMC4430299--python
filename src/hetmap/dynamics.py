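"""Deterministic mean dynamics of two interconverting cell subpopulations.

Two model families describe the sizes x1(t), x2(t) of the subpopulations
(for example Sca-1 high/low fractions of a clonal progenitor population):

* **linear** --  dx1/dt = r x1 - k1 x1 + k2 x2,
                 dx2/dt = r x2 + k1 x1 - k2 x2,
  where r is a common growth rate and k1, k2 the state-transition rates.

* **nonlinear** -- the linear terms plus feedback
  -k3 w2 x1 + k4 w1 x2 on dx1/dt (mirror-signed on dx2/dt), where by
  default w_i = x_i/(x1+x2) is the subpopulation *proportion* (a
  ``w_convention="size"`` switch uses w_i = x_i instead).

Both families conserve total growth: x1 + x2 always grows exactly like
e^{rt} because transition and feedback terms cancel in the sum.

Trajectories are integrated with classical fixed-step fourth-order
Runge-Kutta.  For the linear model RK4 with step h reduces algebraically to
repeated multiplication by the one-step matrix
I + hA + (hA)^2/2 + (hA)^3/6 + (hA)^4/24, which is how it is evaluated
here (identical to explicit stepping up to floating-point roundoff, and
much faster inside the estimation loop).  An exact closed form for the
linear system is provided as an independent oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateStateError,
    DivergenceError,
    InvalidParameterError,
    NegativityWarning,
)

LINEAR = "linear"
NONLINEAR = "nonlinear"
PARAM_NAMES = {LINEAR: ("r", "k1", "k2"), NONLINEAR: ("r", "k1", "k2", "k3", "k4")}


@dataclass(frozen=True)
class ODEParamsLinear:
    """Linear-model parameters: growth rate r, transition rates k1 (x1->x2)
    and k2 (x2->x1)."""

    r: float
    k1: float
    k2: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.r, self.k1, self.k2)):
            raise InvalidParameterError("ODE parameters must be finite")
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidParameterError("transition rates must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.k1, self.k2])


@dataclass(frozen=True)
class ODEParamsNonlinear:
    """Nonlinear-model parameters: r, k1, k2 as in the linear model plus
    feedback rates k3, k4."""

    r: float
    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self):
        vals = (self.r, self.k1, self.k2, self.k3, self.k4)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("ODE parameters must be finite")
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise InvalidParameterError("rates k1..k4 must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.k1, self.k2, self.k3, self.k4])


def params_from_array(model: str, values) -> ODEParamsLinear | ODEParamsNonlinear:
    values = [float(v) for v in np.asarray(values)]
    if model == LINEAR:
        return ODEParamsLinear(*values)
    if model == NONLINEAR:
        return ODEParamsNonlinear(*values)
    raise InvalidParameterError(f"unknown model {model!r}")


@dataclass(frozen=True)
class State:
    """Subpopulation sizes (x1, x2), in arbitrary abundance units."""

    x1: float
    x2: float

    def __post_init__(self):
        if self.x1 < 0 or self.x2 < 0:
            raise InvalidParameterError("initial state must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2])


@dataclass(frozen=True)
class TimeGrid:
    """Observation design: start time t0, observation times, and the RK4
    substep h (which must divide every inter-observation gap)."""

    t0: float = 0.0
    times: tuple = tuple(float(t) for t in range(1, 10))
    h: float = 0.05

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if self.h <= 0:
            raise InvalidParameterError("substep h must be positive")
        prev = self.t0
        for t in times:
            gap = t - prev
            if gap <= 0:
                raise InvalidParameterError(
                    "observation times must be strictly increasing from t0"
                )
            steps = round(gap / self.h)
            if steps < 1 or abs(gap - steps * self.h) > 1e-9:
                raise InvalidParameterError(
                    f"substep h={self.h} does not divide the gap "
                    f"({prev}, {t})"
                )
            prev = t

    @property
    def T(self) -> int:
        return len(self.times)

    def steps_per_gap(self) -> list[int]:
        gaps = np.diff(np.concatenate(([self.t0], self.times)))
        return [round(g / self.h) for g in gaps]


def linear_rhs(s: State | tuple, p: ODEParamsLinear) -> tuple:
    """Right-hand side of the linear model at state s."""
    x1, x2 = (s.x1, s.x2) if isinstance(s, State) else s
    return (
        p.r * x1 - p.k1 * x1 + p.k2 * x2,
        p.r * x2 + p.k1 * x1 - p.k2 * x2,
    )


def nonlinear_rhs(
    s: State | tuple, p: ODEParamsNonlinear, w_convention: str = "proportion"
) -> tuple:
    """Right-hand side of the nonlinear model at state s.

    With the default convention the feedback weights are subpopulation
    proportions w_i = x_i/(x1+x2); ``w_convention="size"`` uses w_i = x_i.
    """
    x1, x2 = (s.x1, s.x2) if isinstance(s, State) else s
    if w_convention == "proportion":
        tot = x1 + x2
        if tot == 0:
            raise DegenerateStateError(
                "x1 + x2 = 0: proportions undefined for the nonlinear model"
            )
        w1, w2 = x1 / tot, x2 / tot
    elif w_convention == "size":
        w1, w2 = x1, x2
    else:
        raise InvalidParameterError(f"unknown w_convention {w_convention!r}")
    fb = -p.k3 * w2 * x1 + p.k4 * w1 * x2
    d1 = p.r * x1 - p.k1 * x1 + p.k2 * x2 + fb
    d2 = p.r * x2 + p.k1 * x1 - p.k2 * x2 - fb
    return (d1, d2)


def _linear_system_matrix(p: ODEParamsLinear) -> np.ndarray:
    return np.array([[p.r - p.k1, p.k2], [p.k1, p.r - p.k2]])


def _rk4_onestep_matrix(A: np.ndarray, h: float) -> np.ndarray:
    """The RK4 one-step propagator for y' = Ay: a degree-4 Taylor polynomial
    in hA (classical RK4 is exact to this polynomial on linear systems)."""
    hA = h * A
    M = np.eye(2) + hA
    P = hA
    for k in (2, 3, 4):
        P = P @ hA / k
        M = M + P
    return M


def solve_rk4(
    model: str,
    p,
    init: State,
    grid: TimeGrid,
    w_convention: str = "proportion",
) -> np.ndarray:
    """Integrate the chosen model with classical RK4 and sample it at the
    observation times.

    Returns the stacked, variable-major mean vector of length 2T:
    (x1(t1)..x1(tT), x2(t1)..x2(tT)).  Raises
    :class:`~hetmap.errors.DivergenceError` if the state becomes
    non-finite, and emits :class:`~hetmap.errors.NegativityWarning` if a
    component falls below -1e-9.
    """
    steps = grid.steps_per_gap()
    T = grid.T
    out = np.empty((T, 2))
    if model == LINEAR:
        M = _rk4_onestep_matrix(_linear_system_matrix(p), grid.h)
        y = init.as_array()
        for k, g in enumerate(steps):
            y = np.linalg.matrix_power(M, g) @ y
            out[k] = y
    elif model == NONLINEAR:
        x1, x2 = init.x1, init.x2
        h = grid.h
        t = grid.t0
        for k, g in enumerate(steps):
            for _ in range(g):
                d1a, d2a = nonlinear_rhs((x1, x2), p, w_convention)
                d1b, d2b = nonlinear_rhs(
                    (x1 + 0.5 * h * d1a, x2 + 0.5 * h * d2a), p, w_convention
                )
                d1c, d2c = nonlinear_rhs(
                    (x1 + 0.5 * h * d1b, x2 + 0.5 * h * d2b), p, w_convention
                )
                d1d, d2d = nonlinear_rhs(
                    (x1 + h * d1c, x2 + h * d2c), p, w_convention
                )
                x1 += h * (d1a + 2 * d1b + 2 * d1c + d1d) / 6.0
                x2 += h * (d2a + 2 * d2b + 2 * d2c + d2d) / 6.0
                t += h
            if not (math.isfinite(x1) and math.isfinite(x2)):
                raise DivergenceError(
                    f"non-finite state at t={grid.times[k]}",
                    time_reached=grid.times[k],
                )
            out[k] = (x1, x2)
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    if not np.all(np.isfinite(out)):
        bad = int(np.where(~np.isfinite(out).all(axis=1))[0][0])
        raise DivergenceError(
            f"non-finite state at t={grid.times[bad]}",
            time_reached=grid.times[bad],
        )
    if out.min() < -1e-9:
        warnings.warn(
            f"trajectory dips to {out.min():.3g} below zero",
            NegativityWarning,
            stacklevel=2,
        )
    return np.concatenate([out[:, 0], out[:, 1]])


def linear_closed_form(p: ODEParamsLinear, init: State, t: float) -> State:
    """Exact solution of the linear model at time t (validation oracle).

    The total s = x1 + x2 grows as s0 e^{rt} while the fraction
    u = x1/s obeys du/dt = k2 - (k1 + k2) u, a scalar linear ODE with
    explicit solution; the system eigenvalues are r and r - k1 - k2.
    """
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    s0 = init.x1 + init.x2
    s = s0 * math.exp(p.r * t)
    if s0 == 0:
        return State(0.0, 0.0)
    ksum = p.k1 + p.k2
    u0 = init.x1 / s0
    if ksum == 0:
        u = u0
    else:
        uinf = p.k2 / ksum
        u = uinf + (u0 - uinf) * math.exp(-ksum * t)
    return State(u * s, (1.0 - u) * s)


def mean_vector(
    model: str,
    p,
    init: State,
    grid: TimeGrid,
    w_convention: str = "proportion",
) -> np.ndarray:
    """Genotype mean trajectory in the stacked variable-major layout used by
    the likelihood and covariance modules (thin wrapper over
    :func:`solve_rk4`)."""
    return solve_rk4(model, p, init, grid, w_convention)
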