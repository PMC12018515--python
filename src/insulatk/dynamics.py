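"""Two-variable linear excitatory-inhibitory dynamics of the insula.

The excitatory population x(t) and inhibitory population y(t) evolve as

    dx/dt = a*x - b*y
    dy/dt = c*x + d*y

i.e. linearly with system matrix A = [[a, -b], [c, d]].  The parameters
(per second) represent synaptic gains: a is excitatory self-excitation,
b the inhibitory-to-excitatory gain, c the excitatory drive onto the
inhibitory population and d the inhibitory leak.  The reference
parameter set a=1.0, b=1.5, c=1.0, d=-1.0 has trace 0 and determinant
0.5, a neutral centre: trajectories are closed orbits with angular
frequency sqrt(0.5) rad/s (period 2*pi/sqrt(0.5) ~ 8.886 s) that
conserve the quadratic form Q(x, y) = x^2 - 2*x*y + 1.5*y^2.

Simulation uses adaptive explicit Runge-Kutta (rtol 1e-9, atol 1e-12)
evaluated on a fixed uniform grid; the matrix-exponential closed form is
the exact solution and serves as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

__all__ = [
    "LinearEIDynamics",
    "TrajectoryEI",
    "FixedPointClass",
    "FixedPointKind",
    "Stability",
    "IntegrationError",
    "default_model",
    "system_matrix",
    "classify",
    "simulate",
    "closed_form",
    "conserved_form",
    "quadratic_value",
    "period",
    "amplitude_bounds",
]

_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Numerical integration failed; the message carries solver diagnostics."""


class FixedPointKind(str, Enum):
    CENTER = "center"
    SPIRAL = "spiral"
    NODE = "node"
    SADDLE = "saddle"
    DEGENERATE = "degenerate"


class Stability(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class LinearEIDynamics:
    """Parameters, initial conditions and time grid of the E-I system."""

    a: float = 1.0
    b: float = 1.5
    c: float = 1.0
    d: float = -1.0
    x0: float = 1.0
    y0: float = 0.5
    t_span: tuple[float, float] = (0.0, 20.0)
    n_points: int = 1000

    def __post_init__(self):
        for name in ("a", "b", "c", "d", "x0", "y0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")
        t0, t1 = self.t_span
        if not (math.isfinite(t0) and math.isfinite(t1) and t1 > t0):
            raise ValueError("t_span must be a finite increasing interval")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def ic(self) -> np.ndarray:
        return np.array([self.x0, self.y0])

    def time_grid(self) -> np.ndarray:
        """Uniform grid of n_points samples including both endpoints."""
        return np.linspace(self.t_span[0], self.t_span[1], self.n_points)


@dataclass(frozen=True)
class TrajectoryEI:
    """Simulated time course of the excitatory and inhibitory populations."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("times, x, y must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def max_abs(self) -> float:
        """Largest absolute activity attained by either population."""
        return float(max(np.abs(self.x).max(), np.abs(self.y).max()))

    def states(self) -> np.ndarray:
        """(n, 2) array of (x, y) states."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class FixedPointClass:
    """Trace-determinant classification of the origin fixed point."""

    kind: FixedPointKind
    stability: Stability
    eigenvalues: tuple[complex, complex]
    trace: float
    det: float


def default_model() -> LinearEIDynamics:
    """Reference parameter set: a=1.0, b=1.5, c=1.0, d=-1.0, IC (1.0, 0.5),
    1000 points on [0, 20] s."""
    return LinearEIDynamics()


def system_matrix(model: LinearEIDynamics) -> np.ndarray:
    """System matrix A = [[a, -b], [c, d]] of the linear E-I equations."""
    return np.array([[model.a, -model.b], [model.c, model.d]])


def classify(model: LinearEIDynamics) -> FixedPointClass:
    """Classify the origin via the trace-determinant plane.

    det < 0: saddle; det ~ 0: degenerate; det > 0 with trace ~ 0: centre
    (neutral); complex eigenvalues otherwise: spiral; real: node.
    Stability follows the sign of the trace.
    """
    A = system_matrix(model)
    tr = float(np.trace(A))
    det = float(np.linalg.det(A))
    eig = np.linalg.eigvals(A)
    scale = max(1.0, float(np.abs(A).max()) ** 2)
    tol = _TOL * scale
    if det < -tol:
        kind, stab = FixedPointKind.SADDLE, Stability.UNSTABLE
    elif abs(det) <= tol:
        kind = FixedPointKind.DEGENERATE
        stab = (
            Stability.STABLE if tr < -tol
            else Stability.UNSTABLE if tr > tol
            else Stability.NEUTRAL
        )
    elif abs(tr) <= tol:
        kind, stab = FixedPointKind.CENTER, Stability.NEUTRAL
    else:
        disc = tr * tr - 4.0 * det
        kind = FixedPointKind.SPIRAL if disc < 0 else FixedPointKind.NODE
        stab = Stability.STABLE if tr < 0 else Stability.UNSTABLE
    return FixedPointClass(
        kind=kind,
        stability=stab,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        trace=tr,
        det=det,
    )


def simulate(model: LinearEIDynamics, rtol: float = 1e-9, atol: float = 1e-12) -> TrajectoryEI:
    """Integrate the system on the model's time grid with adaptive RK45."""
    A = system_matrix(model)
    sol = solve_ivp(
        lambda t, s: A @ s,
        model.t_span,
        model.ic,
        method="RK45",
        t_eval=model.time_grid(),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solve_ivp failed: {sol.message}")
    return TrajectoryEI(times=sol.t, x=sol.y[0], y=sol.y[1])


def closed_form(model: LinearEIDynamics, t) -> np.ndarray:
    """Exact solution exp(A t) @ (x0, y0) at scalar or array times.

    Uses the eigendecomposition when A is diagonalizable; falls back to
    a per-time matrix exponential otherwise.  Returns shape (2,) for a
    scalar time, (n, 2) for an array.
    """
    A = system_matrix(model)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    ic = model.ic.astype(complex)
    w, V = np.linalg.eig(A)
    use_eig = np.linalg.cond(V) < 1e8
    if use_eig:
        coef = np.linalg.solve(V, ic)
        states = (V @ (np.exp(np.outer(w, t_arr)) * coef[:, None])).T
        states = np.real_if_close(states, tol=1e6).real
    else:  # defective matrix, e.g. a shear
        states = np.array([linalg.expm(A * tk) @ model.ic for tk in t_arr])
    return states[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else states


def conserved_form(model: LinearEIDynamics) -> tuple[float, float, float]:
    """Coefficients (alpha, beta, gamma) of the conserved quadratic form.

    For a centre (trace 0, det > 0) the orbits conserve
    Q(x, y) = alpha*x^2 + beta*x*y + gamma*y^2, normalized to alpha = 1.
    Writing A = [[p, q], [r, -p]], stationarity of Q along the flow gives
    beta = -2p/r, gamma = -q/r (r is nonzero for every centre).
    """
    fp = classify(model)
    if fp.kind is not FixedPointKind.CENTER:
        raise ValueError(
            f"no conserved quadratic form: system is a {fp.kind.value}, not a center"
        )
    A = system_matrix(model)
    p, q, r = A[0, 0], A[0, 1], A[1, 0]
    return (1.0, float(-2.0 * p / r), float(-q / r))


def quadratic_value(coeffs: tuple[float, float, float], x, y):
    """Evaluate Q(x, y) = alpha*x^2 + beta*x*y + gamma*y^2."""
    alpha, beta, gamma = coeffs
    return alpha * np.asarray(x) ** 2 + beta * np.asarray(x) * np.asarray(y) + gamma * np.asarray(y) ** 2


def period(model: LinearEIDynamics) -> float:
    """Orbital period 2*pi/|Im(lambda)| of a centre."""
    fp = classify(model)
    if fp.kind is not FixedPointKind.CENTER:
        raise ValueError(f"system is a {fp.kind.value}; period is defined only for a center")
    omega = abs(fp.eigenvalues[0].imag)
    return 2.0 * math.pi / omega


def amplitude_bounds(model: LinearEIDynamics, ic=None) -> tuple[float, float]:
    """Exact per-coordinate amplitude extremes on the invariant orbit.

    On the conserved ellipse Q = Q0 through the initial condition,
    max x^2 = Q0 * (Q^-1)_11 and max y^2 = Q0 * (Q^-1)_22 where Q is the
    symmetric matrix of the quadratic form.  For the reference model and
    IC (1.0, 0.5): max|x| = sqrt(1.125) ~ 1.0607, max|y| = sqrt(0.75)
    ~ 0.8660 — inside the conventional plotting range of +/-1.1.
    """
    coeffs = conserved_form(model)
    ic = model.ic if ic is None else np.asarray(ic, dtype=float)
    q0 = float(quadratic_value(coeffs, ic[0], ic[1]))
    alpha, beta, gamma = coeffs
    Qm = np.array([[alpha, beta / 2.0], [beta / 2.0, gamma]])
    Qinv = np.linalg.inv(Qm)
    return (float(np.sqrt(q0 * Qinv[0, 0])), float(np.sqrt(q0 * Qinv[1, 1])))
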