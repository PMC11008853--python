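"""Three-compartment diffusion–convection model of transdermal penetration.

The skin (donor side → receptor perfusate) is discretized into three
well-mixed compartments with concentrations ``x1, x2, x3``.  Drug enters
compartment 1 at a constant rate ``k_in`` (infinite-dose donor), moves
between neighbouring compartments by diffusion (``k_d``, symmetric) and
convection (``k_c``, directed towards the receptor), and leaves the last
compartment into the perfusate at rate ``k_out``:

    dx1/dt = k_in + k_d·x2 − (k_d + k_c)·x1
    dx2/dt = (k_d + k_c)·x1 + k_d·x3 − (2k_d + k_c)·x2
    dx3/dt = (k_d + k_c)·x2 − (k_d + k_out)·x3

Only ``y = x3`` is observed.  Time is in hours, rates per hour; state and
``k_in`` carry the units of the measured series (e.g. μg/cm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "RateParameters",
    "Trajectory",
    "ObservationSeries",
    "ObservationMode",
    "compute_derivative",
    "system_matrices",
    "simulate_closed_form",
    "simulate_numeric",
    "steady_state",
    "observe",
]


@dataclass(frozen=True)
class RateParameters:
    """The four transport rates of the model.

    Attributes
    ----------
    k_in : float
        Constant inflow into compartment 1 (observable units per hour).
    k_d : float
        Diffusion rate constant (1/h), symmetric between neighbours.
    k_c : float
        Convection rate constant (1/h), directed towards the receptor.
    k_out : float
        First-order outflow from compartment 3 into the perfusate (1/h).
    """

    k_in: float
    k_d: float
    k_c: float
    k_out: float

    def __post_init__(self) -> None:
        for name in ("k_in", "k_d", "k_c", "k_out"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"rate {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"rate {name} must be nonnegative, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_in, self.k_d, self.k_c, self.k_out])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "RateParameters":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected 4 rates, got shape {a.shape}")
        return cls(*a)

    def all_positive(self) -> bool:
        return all(v > 0 for v in self.as_array())

    def scaled(self, factor: float) -> "RateParameters":
        """Scale the inflow only (the response from x0 = 0 is linear in k_in)."""
        return replace(self, k_in=self.k_in * factor)


class ObservationMode(str, Enum):
    """How the measured series relates to the state.

    ``direct``: the observable is the third state, y(t) = x3(t) — the mode
    used throughout the model-calibration workflow.
    ``cumulative_outflow``: the running integral of the outflow flux,
    M(t) = ∫ k_out·x3 ds, for users who prefer an explicit collected-mass
    bookkeeping; provided because chip data are cumulative masses.
    """

    DIRECT = "direct"
    CUMULATIVE_OUTFLOW = "cumulative_outflow"


@dataclass(frozen=True)
class Trajectory:
    """Compartment concentrations on a time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3)
    params: RateParameters

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if x.shape != (t.size, 3):
            raise ValueError(f"states must have shape ({t.size}, 3), got {x.shape}")

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]


@dataclass(frozen=True)
class ObservationSeries:
    """A measured or simulated observable on a sample grid."""

    times: np.ndarray
    values: np.ndarray
    unit: str = "ug/cm^2"
    replicate: int = 0
    scenario_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("observation values must be finite")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def endpoint(self) -> float:
        return float(self.values[-1])


def _validate_state(state: Sequence[float]) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (3,):
        raise ValueError(f"state must have 3 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    return x


def system_matrices(params: RateParameters) -> tuple[np.ndarray, np.ndarray]:
    """Linear-system form ``x' = A x + b`` of the model.

    ``A`` is Metzler (nonnegative off-diagonal) and ``b = (k_in, 0, 0)``.
    """
    kd, kc, ko = params.k_d, params.k_c, params.k_out
    A = np.array(
        [
            [-(kd + kc), kd, 0.0],
            [kd + kc, -(2 * kd + kc), kd],
            [0.0, kd + kc, -(kd + ko)],
        ]
    )
    b = np.array([params.k_in, 0.0, 0.0])
    return A, b


def compute_derivative(state: Sequence[float], params: RateParameters) -> np.ndarray:
    """Right-hand side (dx1, dx2, dx3) at ``state``."""
    x = _validate_state(state)
    A, b = system_matrices(params)
    return A @ x + b


def _grid(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be nonnegative and strictly increasing")
    return t


def simulate_closed_form(
    params: RateParameters, x0: Sequence[float], times: Sequence[float]
) -> Trajectory:
    """Exact solution of the linear system on the grid.

    When ``A`` is invertible the affine shift is used,
    ``x(t) = e^{At}(x0 + A⁻¹b) − A⁻¹b``; a singular ``A`` (some rates zero)
    falls back to the exponential of the augmented homogeneous system
    ``d/dt (x, 1) = [[A, b], [0, 0]] (x, 1)``, which is exact in all cases.
    """
    x = _validate_state(x0)
    t = _grid(times)
    A, b = system_matrices(params)
    states = np.empty((t.size, 3))
    try:
        shift = np.linalg.solve(A, b)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if not singular and np.linalg.cond(A) < 1e12:
        z0 = x + shift
        for i, ti in enumerate(t):
            states[i] = expm(A * ti) @ z0 - shift
    else:
        M = np.zeros((4, 4))
        M[:3, :3] = A
        M[:3, 3] = b
        z0 = np.append(x, 1.0)
        for i, ti in enumerate(t):
            states[i] = (expm(M * ti) @ z0)[:3]
    return Trajectory(times=t, states=states, params=params)


def simulate_numeric(
    params: RateParameters,
    x0: Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> Trajectory:
    """Numerically integrated trajectory (LSODA), independent of the
    matrix-exponential path; used as a cross-check oracle in the tests."""
    x = _validate_state(x0)
    t = _grid(times)
    A, b = system_matrices(params)
    t_eval = t
    t0 = 0.0 if t[0] > 0 else t[0]
    sol = solve_ivp(
        lambda _t, y: A @ y + b,
        (t0, t[-1]),
        x,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=t, states=sol.y.T, params=params)


def steady_state(params: RateParameters) -> np.ndarray:
    """Equilibrium ``x*`` solving ``A x + b = 0``.

    Requires ``k_out > 0`` and ``k_d + k_c > 0`` (otherwise ``A`` is singular
    and no finite equilibrium exists for ``k_in > 0``).  Mass balance forces
    ``x3* = k_in / k_out``.
    """
    if params.k_out <= 0:
        raise ValueError("steady state requires k_out > 0 (outflow closes the mass balance)")
    if params.k_d + params.k_c <= 0:
        raise ValueError("steady state requires k_d + k_c > 0 (transport between compartments)")
    A, b = system_matrices(params)
    return np.linalg.solve(A, -b)


def observe(
    trajectory: Trajectory,
    mode: ObservationMode | str = ObservationMode.DIRECT,
    **series_kwargs,
) -> ObservationSeries:
    """Project a trajectory onto the measured series.

    ``direct`` returns y(t) = x3(t).  ``cumulative_outflow`` returns the
    trapezoidal running integral M(t) = ∫₀ᵗ k_out·x3(s) ds on the grid.
    """
    mode = ObservationMode(mode)
    if mode is ObservationMode.DIRECT:
        values = trajectory.x3.copy()
    else:
        flux = trajectory.params.k_out * trajectory.x3
        t = trajectory.times
        increments = 0.5 * (flux[1:] + flux[:-1]) * np.diff(t)
        values = np.concatenate([[0.0], np.cumsum(increments)])
        if t[0] > 0:  # integral from 0 to the first grid point, x3(0)=x3(t0) held
            values = values + trajectory.params.k_out * trajectory.x3[0] * t[0]
    return ObservationSeries(times=trajectory.times, values=values, **series_kwargs)
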