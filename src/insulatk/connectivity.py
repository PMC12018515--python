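"""Weighted directed connectivity network of the insula.

Five regions — insula, prefrontal cortex (PFC), amygdala, anterior
cingulate cortex (ACC) and thalamus — are linked by a 5x5 weighted
matrix W in which w_ij is the directed connection strength from region i
to region j, weights lie in [0, 1] and the diagonal is zero (no
self-connections).  The packaged matrix encodes strong insula output to
the PFC (w12 = 0.8) and the ACC (w14 = 0.6) with PFC feedback w21 = 0.7.

Network activity follows a linear rate model

    ds/dt = -gamma * s + W^T s + u

where gamma >= 0 is a uniform leak rate, u a constant per-region drive,
and W^T appears because row i of W lists region i's outgoing weights.
By the Gershgorin circle theorem every eigenvalue of W^T - gamma*I has
real part <= max_i(row-sum_i of W) - gamma, so a leak exceeding the
largest out-strength (2.3 for the packaged matrix) guarantees decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import IntegrationError

__all__ = [
    "ConnectivityMatrix",
    "NetworkTrajectory",
    "StabilityReport",
    "ValidationError",
    "packaged_matrix",
    "validate",
    "simulate_network",
    "stability_report",
]

REGION_ORDER = ("insula", "prefrontal cortex", "amygdala", "ACC", "thalamus")

_PACKAGED_W = np.array(
    [
        [0.0, 0.8, 0.5, 0.6, 0.4],
        [0.7, 0.0, 0.4, 0.5, 0.3],
        [0.6, 0.3, 0.0, 0.4, 0.2],
        [0.5, 0.4, 0.3, 0.0, 0.6],
        [0.3, 0.2, 0.1, 0.5, 0.0],
    ]
)

_TOL = 1e-9


class ValidationError(ValueError):
    """A connectivity matrix violated its structural constraints."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(problems))


def _check(labels, W) -> list[str]:
    problems = []
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        return [f"matrix must be square, got shape {W.shape}"]
    n = W.shape[0]
    if len(labels) != n:
        problems.append(f"{len(labels)} labels for a {n}x{n} matrix")
    if len(set(labels)) != len(labels):
        problems.append("labels must be unique")
    if not np.all(np.isfinite(W)):
        bad = np.argwhere(~np.isfinite(W))
        problems.extend(f"non-finite entry at {tuple(ij + 1)}" for ij in bad)
    else:
        diag = np.flatnonzero(np.diag(W) != 0.0)
        problems.extend(f"nonzero diagonal at ({i + 1},{i + 1})" for i in diag)
        bad = np.argwhere((W < 0.0) | (W > 1.0))
        problems.extend(
            f"weight {W[tuple(ij)]} outside [0,1] at {tuple(ij + 1)}" for ij in bad
        )
    return problems


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Labelled weighted directed connectivity matrix with zero diagonal."""

    labels: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self):
        labels = tuple(str(lb) for lb in self.labels)
        W = np.asarray(self.W, dtype=float)
        problems = _check(labels, W)
        if problems:
            raise ValidationError(problems)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return len(self.labels)

    def weight(self, source: str, target: str) -> float:
        """Directed weight from ``source`` to ``target`` by label."""
        i = self.labels.index(source)
        j = self.labels.index(target)
        return float(self.W[i, j])

    def strengths(self) -> pd.DataFrame:
        """Out-strength (row sum) and in-strength (column sum) per region."""
        return pd.DataFrame(
            {
                "out_strength": self.W.sum(axis=1),
                "in_strength": self.W.sum(axis=0),
            },
            index=list(self.labels),
        ).rename_axis("region")

    def asymmetry(self) -> np.ndarray:
        """Antisymmetric matrix of directed imbalances w_ij - w_ji."""
        return self.W - self.W.T

    def permuted(self, order: list[int]) -> "ConnectivityMatrix":
        """Consistently reorder labels, rows and columns."""
        idx = np.asarray(order)
        return ConnectivityMatrix(
            labels=tuple(self.labels[i] for i in idx), W=self.W[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConnectivityMatrix":
        return cls(labels=tuple(str(c) for c in df.columns), W=df.to_numpy(dtype=float))

    def edge_list(self) -> list[dict]:
        """Nonzero directed edges as [{from, to, weight}, ...]."""
        return [
            {"from": self.labels[i], "to": self.labels[j], "weight": float(self.W[i, j])}
            for i in range(self.n)
            for j in range(self.n)
            if self.W[i, j] != 0.0
        ]


@dataclass(frozen=True)
class NetworkTrajectory:
    """Simulated per-region activity of the linear rate network."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_regions)
    labels: tuple[str, ...]
    leak: float
    drive: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if s.shape != (len(t), len(self.labels)):
            raise ValueError("states must have shape (n_times, n_regions)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        object.__setattr__(self, "drive", np.asarray(self.drive, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "t", self.times)
        return df


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum of the network Jacobian W^T - gamma*I."""

    eigenvalues: np.ndarray
    max_real: float
    stable: bool
    marginal: bool
    leak: float


def packaged_matrix() -> ConnectivityMatrix:
    """The packaged 5-region connectivity matrix, rows = outgoing weights.

    Region order [insula, PFC, amygdala, ACC, thalamus] is fixed by the
    identifications w12 = 0.8 (insula -> PFC) and w14 = 0.6 (insula -> ACC).
    """
    return ConnectivityMatrix(labels=REGION_ORDER, W=_PACKAGED_W.copy())


def validate(labels, W) -> list[str]:
    """Structural problems of a candidate matrix; empty list means valid."""
    return _check(tuple(str(lb) for lb in labels), W)


def simulate_network(
    conn: ConnectivityMatrix,
    leak: float = 1.0,
    drive=None,
    ic=None,
    t_span: tuple[float, float] = (0.0, 20.0),
    n_points: int = 1000,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> NetworkTrajectory:
    """Integrate ds/dt = -leak*s + W^T s + drive on a uniform grid.

    Defaults: leak 1.0, zero drive, initial condition (1, 0, 0, ..., 0)
    — a unit pulse in the first region (the insula for the packaged
    matrix).  Same adaptive RK45 contract as the E-I simulator.
    """
    if not (math.isfinite(leak) and leak >= 0):
        raise ValueError("leak must be finite and >= 0")
    n = conn.n
    u = np.zeros(n) if drive is None else np.asarray(drive, dtype=float)
    s0 = np.array([1.0] + [0.0] * (n - 1)) if ic is None else np.asarray(ic, dtype=float)
    if u.shape != (n,) or s0.shape != (n,):
        raise ValueError(f"drive and ic must be length-{n} vectors")
    J = conn.W.T - leak * np.eye(n)
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(
        lambda t, s: J @ s + u,
        t_span,
        s0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solve_ivp failed: {sol.message}")
    return NetworkTrajectory(
        times=sol.t, states=sol.y.T, labels=conn.labels, leak=float(leak), drive=u
    )


def stability_report(conn: ConnectivityMatrix, leak: float) -> StabilityReport:
    """Eigenvalues of W^T - leak*I; stable iff every real part is negative.

    A spectrum whose largest real part sits at zero (within tolerance)
    is flagged marginal and reported not stable.
    """
    J = conn.W.T - leak * np.eye(conn.n)
    eig = np.linalg.eigvals(J)
    max_real = float(eig.real.max())
    marginal = abs(max_real) <= _TOL
    return StabilityReport(
        eigenvalues=eig,
        max_real=max_real,
        stable=bool(max_real < -_TOL),
        marginal=marginal,
        leak=float(leak),
    )
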