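"""Coupled-logistic latent dynamics.

The disease state is a low-dimensional vector of modality z-scores
``z = (z_amy, z_met, z_atr, z_cli)`` whose joint evolution follows

    dz_m/dt = k_m z_m (1 - z_m) + sum_{j != m} alpha_{m,j} z_j

i.e. a logistic self-term with progression rate ``k_m`` (1/year) plus linear
cross-modality couplings ``alpha_{m,j}`` (coordinate j drives coordinate m).
In matrix form ``dz/dt = W z - V z**2`` with ``W`` carrying the rates on the
diagonal and the couplings off-diagonal, and ``V = diag(diag(W))`` (the square
is elementwise).

Hypothetical interventions damp selected components of the vector field with a
diagonal matrix ``Gamma = diag(gamma_1, ..., gamma_M)``, ``0 <= gamma_m <= 1``:
``gamma_amy = 0`` is a 100% amyloid-lowering intervention (accumulation fully
arrested), ``gamma_amy = 0.5`` a 50% one.

Integration is fixed-step classical Runge-Kutta (RK4, default step 0.1 year);
times before the initial condition are reached by stepping with a negative
step, which is the time-reversed flow.  The state is not clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DynamicsParams",
    "InterventionSpec",
    "Trajectory",
    "IntegrationDivergedError",
    "vector_field",
    "vector_field_elementwise",
    "apply_intervention_field",
    "integrate",
    "rk4_step",
]

#: default integrator step, years
DEFAULT_STEP = 0.1


class IntegrationDivergedError(RuntimeError):
    """Raised when the numerical solution leaves the finite range."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"latent ODE solution diverged (non-finite state) near t={time:.3f} years")


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters ``W`` of the coupled-logistic system.

    ``W`` is M x M: diagonal entries are the logistic progression rates
    ``k_m`` (1/year), off-diagonal entry ``W[m, j]`` is the coupling
    ``alpha_{m,j}`` of coordinate j into coordinate m.  ``V`` is derived as
    ``diag(diag(W))`` and never stored independently.
    """

    W: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be a square matrix, got shape {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("W must be finite")
        W = W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "W", W)

    @property
    def M(self) -> int:
        return self.W.shape[0]

    @property
    def rates(self) -> np.ndarray:
        """The logistic rates k_m (diagonal of W, equal to the diagonal of V)."""
        return np.diag(self.W)

    @property
    def V(self) -> np.ndarray:
        return np.diag(np.diag(self.W))

    @property
    def couplings(self) -> np.ndarray:
        """Off-diagonal couplings alpha_{m,j}; zero diagonal."""
        A = self.W.copy()
        np.fill_diagonal(A, 0.0)
        return A


@dataclass(frozen=True)
class InterventionSpec:
    """Per-modality damping of the vector field from ``start_time`` on.

    ``gammas[m]`` multiplies component m of dz/dt while the intervention is
    active; the intervention is irreversible by default (``end_time`` = +inf).
    Times are years relative to conversion (t = 0).
    """

    gammas: np.ndarray
    start_time: float
    end_time: float = math.inf

    def __post_init__(self):
        g = np.asarray(self.gammas, dtype=float)
        if g.ndim != 1:
            raise ValueError("gammas must be a vector")
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("every gamma must lie in [0, 1]")
        if not self.start_time < self.end_time:
            raise ValueError("start_time must precede end_time")
        g = g.copy()
        g.flags.writeable = False
        object.__setattr__(self, "gammas", g)

    def active(self, t: float) -> bool:
        return self.start_time <= t < self.end_time


@dataclass(frozen=True)
class Trajectory:
    """Solution of the latent ODE on a strictly increasing time grid.

    ``states`` has shape ``(len(times), ..., M)``; the optional middle axes
    carry an ensemble/batch of solutions sharing the grid.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or len(t) != s.shape[0]:
            raise ValueError("times and states must have matching leading length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]


def _check_state(z: np.ndarray, M: int) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != M:
        raise ValueError(f"state has trailing dimension {z.shape[-1]}, dynamics expect {M}")
    return z


def vector_field(z: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """dz/dt = W z - V z**2 evaluated at ``z`` (shape ``(..., M)``)."""
    z = _check_state(z, params.M)
    return z @ params.W.T - params.rates * z**2


def vector_field_elementwise(z: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """Per-coordinate form ``k_m z_m (1 - z_m) + sum_{j!=m} alpha_{m,j} z_j``.

    Mathematically identical to :func:`vector_field`; kept as the literal
    coordinate-wise definition for validation.
    """
    z = _check_state(z, params.M)
    k = params.rates
    return k * z * (1.0 - z) + z @ params.couplings.T


def apply_intervention_field(
    z: np.ndarray, params: DynamicsParams, spec: InterventionSpec, t: float
) -> np.ndarray:
    """Vector field under intervention: ``Gamma @ g(z)`` while active, else ``g(z)``."""
    if spec.gammas.shape[-1] != params.M:
        raise ValueError("intervention dimension does not match dynamics")
    g = vector_field(z, params)
    if spec.active(t):
        return spec.gammas * g
    return g


def rk4_step(
    z: np.ndarray,
    h: float,
    params: DynamicsParams,
    gammas: np.ndarray | None = None,
) -> np.ndarray:
    """One classical Runge-Kutta step of (possibly damped) length ``h``.

    When ``gammas`` is given the damped field ``Gamma * g`` is used for the
    whole step: the per-step modulation of the derivative.
    """
    def f(y):
        g = vector_field(y, params)
        return g if gammas is None else gammas * g

    k1 = f(z)
    k2 = f(z + 0.5 * h * k1)
    k3 = f(z + 0.5 * h * k2)
    k4 = f(z + h * k3)
    return z + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _march(z, t_from, t_to, params, intervention, step):
    """Advance ``z`` from ``t_from`` to ``t_to`` with substeps of at most ``step``."""
    span = t_to - t_from
    if span == 0.0:
        return z
    n_sub = max(1, int(math.ceil(abs(span) / step - 1e-12)))
    h = span / n_sub
    t = t_from
    with np.errstate(over="ignore", invalid="ignore"):  # divergence is detected below
        for _ in range(n_sub):
            gam = None
            if intervention is not None and intervention.active(t):
                gam = intervention.gammas
            z = rk4_step(z, h, params, gam)
            t += h
            if not np.all(np.isfinite(z)):
                raise IntegrationDivergedError(t)
    return z


def integrate(
    z0: np.ndarray,
    t0: float,
    t_grid: np.ndarray,
    params: DynamicsParams,
    intervention: InterventionSpec | None = None,
    step: float = DEFAULT_STEP,
) -> Trajectory:
    """Solve the latent ODE from ``z(t0) = z0`` on ``t_grid``.

    Grid times before ``t0`` are reached by integrating the time-reversed
    flow (negative RK4 steps).  ``z0`` may be batched (``(..., M)``): all
    members share the grid.  Interventions modulate the field with ``Gamma``
    at every substep whose start time falls in the active window.
    """
    z0 = _check_state(z0, params.M)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if not (np.all(np.isfinite(t_grid)) and np.all(np.isfinite(z0)) and np.isfinite(t0)):
        raise ValueError("t0, t_grid and z0 must be finite")
    if step <= 0:
        raise ValueError("step must be positive")

    states = np.empty(t_grid.shape[:1] + z0.shape, dtype=float)
    fwd = np.nonzero(t_grid >= t0)[0]
    bwd = np.nonzero(t_grid < t0)[0]
    z, t = z0, t0
    for i in fwd:
        z = _march(z, t, float(t_grid[i]), params, intervention, step)
        t = float(t_grid[i])
        states[i] = z
    z, t = z0, t0
    for i in bwd[::-1]:
        z = _march(z, t, float(t_grid[i]), params, intervention, step)
        t = float(t_grid[i])
        states[i] = z
    return Trajectory(times=t_grid, states=states)
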