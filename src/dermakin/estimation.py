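"""Calibration of the transport rates to measured penetration curves.

The fit minimizes the normalized least-squares objective

    V = ‖y_m − y_c‖₂ / ‖y_m‖₂

over the four positive rates, where y_m is the measured and y_c the model
observable on the sample grid.  Rates are searched within a physiological
box (default [1e-3, 1e3] per hour) by a hybrid trust-region least-squares
solve — a log-space descent that traverses decades cheaply, then a raw-space
polish in which a boundary rate is an ordinary point; robustness against
local minima comes from a seeded multi-start with log-uniform initial
points (200 by default) plus deterministic refinement restarts.  A
descriptive two-segment
continuous piecewise-linear regression captures the slow (release) and
rapid (absorption) phases of a cumulative penetration curve without any
mechanistic assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

from .model import (
    ObservationMode,
    ObservationSeries,
    RateParameters,
    observe,
    simulate_closed_form,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "TwoPhaseFit",
    "RecoveryReport",
    "RECOVERY_REFERENCE_TRUTH",
    "add_sampling_noise",
    "model_observable",
    "objective_value",
    "single_fit",
    "multistart_fit",
    "parameter_recovery_experiment",
    "two_phase_regression",
]

_LOG_BOUND = np.log(1e8)  # optimizer box in log-rate space


@dataclass(frozen=True)
class FitConfig:
    """Settings for single- and multi-start calibration."""

    n_starts: int = 200
    start_bounds: tuple[float, float] = (1e-3, 1e3)
    rate_bounds: tuple[float, float] = (1e-3, 1e3)
    tol: float = 1e-10
    max_evals: int = 2000
    seed: int = 0
    mode: ObservationMode = ObservationMode.DIRECT
    estimate_x0: bool = False  # co-estimate x1(0), x2(0); experimental

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for lo, hi in (self.start_bounds, self.rate_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start calibration."""

    params: RateParameters
    v_min: float
    per_start_v: np.ndarray
    converged: np.ndarray
    fraction_at_minimum: float  # share of starts within 1e-6 of v_min
    seed: int
    fitted: ObservationSeries
    x0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def to_frame(self) -> pd.DataFrame:
        """One-row summary mirroring a per-series parameter table."""
        k = self.params
        return pd.DataFrame(
            [
                {
                    "k_in": k.k_in,
                    "k_d": k.k_d,
                    "k_c": k.k_c,
                    "k_out": k.k_out,
                    "V_min": self.v_min,
                    "n_starts": self.per_start_v.size,
                    "fraction_at_minimum": self.fraction_at_minimum,
                    "seed": self.seed,
                }
            ]
        )


def model_observable(
    params: RateParameters,
    times: np.ndarray,
    x0: Sequence[float] = (0.0, 0.0, 0.0),
    mode: ObservationMode = ObservationMode.DIRECT,
) -> np.ndarray:
    """Model observable on a grid; uniform grids use a single-step
    propagator (one matrix exponential) for speed inside the optimizer."""
    t = np.asarray(times, dtype=float)
    from .model import system_matrices  # local import keeps module load light

    diffs = np.diff(t)
    uniform = t.size > 1 and np.allclose(diffs, diffs[0], rtol=1e-9, atol=0.0)
    if uniform and mode is ObservationMode.DIRECT:
        A, b = system_matrices(params)
        h = float(diffs[0])
        M = np.zeros((4, 4))
        M[:3, :3] = A * h
        M[:3, 3] = b * h
        E = expm(M)
        z = np.empty(4)
        z[:3] = np.asarray(x0, dtype=float)
        z[3] = 1.0
        # step from t=0 to the first grid point, then along the grid
        if t[0] > 0:
            M0 = np.zeros((4, 4))
            M0[:3, :3] = A * t[0]
            M0[:3, 3] = b * t[0]
            z = expm(M0) @ z
        y = np.empty(t.size)
        y[0] = z[2]
        for i in range(1, t.size):
            z = E @ z
            y[i] = z[2]
        return y
    traj = simulate_closed_form(params, x0, t)
    return observe(traj, mode).values


def objective_value(
    y_measured: ObservationSeries, y_computed: ObservationSeries
) -> float:
    """Normalized residual V = ‖y_m − y_c‖₂ / ‖y_m‖₂ (dimensionless)."""
    if y_measured.times.shape != y_computed.times.shape or not np.allclose(
        y_measured.times, y_computed.times
    ):
        raise ValueError("measured and computed series must share the time grid")
    norm = float(np.linalg.norm(y_measured.values))
    if norm == 0.0:
        raise ValueError("objective undefined: measured series is identically zero")
    return float(np.linalg.norm(y_measured.values - y_computed.values) / norm)


def _residual_factory(data: ObservationSeries, config: FitConfig):
    """Residual in raw parameter space: p[:4] are the rates, p[4:6] the
    optional co-estimated x1(0), x2(0)."""
    ym = data.values
    norm = float(np.linalg.norm(ym))
    if norm == 0.0:
        raise ValueError("objective undefined: measured series is identically zero")
    t = data.times
    n_extra = 2 if config.estimate_x0 else 0

    def residual(p: np.ndarray) -> np.ndarray:
        k = RateParameters.from_array(p[:4])
        if n_extra:
            x0 = np.array([p[4], p[5], 0.0])
        else:
            x0 = np.zeros(3)
        yc = model_observable(k, t, x0=x0, mode=config.mode)
        return (yc - ym) / norm

    return residual, n_extra


def _local_solve(residual, p0: np.ndarray, config: FitConfig):
    """Hybrid two-phase local solve.

    Phase 1 descends in log-coordinates (traverses decades of rate space
    cheaply from arbitrary starts); phase 2 polishes in the raw bounded
    space, where a rate that the data push to exactly zero is an ordinary
    boundary point rather than an infinitely distant one.
    """
    lo, hi = config.rate_bounds
    p0 = np.clip(p0, lo, hi)

    def log_residual(z):
        return residual(np.exp(z))

    a = least_squares(
        log_residual,
        np.log(p0),
        bounds=(np.log(lo), np.log(hi)),
        method="trf",
        ftol=config.tol,
        xtol=config.tol,
        gtol=config.tol,
        max_nfev=min(300, config.max_evals),
        x_scale="jac",
    )
    b = least_squares(
        residual,
        np.exp(a.x),
        bounds=(lo, hi),
        method="trf",
        ftol=config.tol,
        xtol=config.tol,
        gtol=config.tol,
        max_nfev=max(config.max_evals - a.nfev, 100),
        x_scale="jac",
    )
    va, vb = float(np.linalg.norm(a.fun)), float(np.linalg.norm(b.fun))
    if vb <= va:
        return b.x, vb, bool(b.status > 0)
    return np.exp(a.x), va, bool(a.status > 0)


def _restart_ladder(p: np.ndarray) -> list[np.ndarray]:
    """Deterministic refinement restarts from a converged point.

    The stiff direction of this model is the diffusion/convection split at
    a nearly fixed total transport rate s = k_d + k_c: local searches can
    stall on the k_c = 0 (pure-diffusion) boundary, a genuine but inferior
    local minimum.  The ladder re-explores complementary splits of s (role
    swap, convection- and diffusion-dominated) and re-centers any rate
    pinned at the box edge, keeping the solve deterministic.
    """
    kin, kd, kc, ko = p[:4]
    s = kd + kc
    cands = [
        np.array([kin, kc, kd, ko]),  # swap diffusion and convection
        np.array([kin, 0.05 * s, 0.95 * s, ko]),
        np.array([kin, 0.95 * s, 0.05 * s, ko]),
    ]
    recenter = p[:4].copy()
    recenter[(recenter <= 1.01e-3) | (recenter >= 0.99e3)] = 1.0
    cands.append(recenter)
    return [np.concatenate([c, p[4:]]) for c in cands]


def _varpro_scan(
    data: ObservationSeries, config: FitConfig, n_grid: int = 8, n_top: int = 4
) -> list[np.ndarray]:
    """Coarse scan of the three shape rates with the inflow profiled out.

    From the drug-free initial state the observable is exactly linear in
    k_in, so for each (k_d, k_c, k_out) on a log grid the optimal inflow
    is the closed-form projection ⟨ŷ, y_m⟩/⟨ŷ, ŷ⟩ of the data onto the
    unit-inflow curve ŷ.  Returns the ``n_top`` best, mutually distant,
    grid points in log space (several basins can score similarly on a
    coarse grid, so a single winner is not enough).
    """
    t, ym = data.times, data.values
    axis = np.geomspace(config.start_bounds[0], config.start_bounds[1], n_grid)
    scored: list[tuple[float, np.ndarray]] = []
    for kd in axis:
        for kc in axis:
            for ko in axis:
                y1 = model_observable(RateParameters(1.0, kd, kc, ko), t)
                denom = float(y1 @ y1)
                kin = max(float(y1 @ ym) / denom, 1e-8) if denom > 0 else 1e-8
                v = float(np.linalg.norm(kin * y1 - ym))
                scored.append((v, np.array([kin, kd, kc, ko])))
    scored.sort(key=lambda t: t[0])
    picked: list[np.ndarray] = []
    for _, p in scored:
        if all(np.linalg.norm(np.log(p[1:] / q[1:])) > 2.0 for q in picked):
            picked.append(p)
        if len(picked) == n_top:
            break
    return picked


def _refine(residual, data, config, p_best, v_best, ok, shared):
    """Stages 2–3 of the robust solve: variable-projection scan restarts,
    then the split-redistribution ladder.  Deterministic; results from an
    identical stalled point are memoized in ``shared`` across the starts
    of a multi-start run (the refinement depends only on that point)."""
    # stalled points from different starts land in the same basin with tiny
    # coordinate scatter; a coarse log-scale key lets them share a refinement
    key = tuple(np.round(np.log10(np.maximum(p_best, 1e-12)), 3))
    if shared is not None and key in shared["refined"]:
        p2, v2, ok2 = shared["refined"][key]
        return (p2, v2, ok or ok2) if v2 < v_best else (p_best, v_best, ok)
    entry = (p_best, v_best, ok)
    can_scan = p_best.size == 4 and config.mode is ObservationMode.DIRECT
    if can_scan:
        if shared is not None:
            if shared["scan"] is None:
                shared["scan"] = _varpro_scan(data, config)
            scan_points = shared["scan"]
        else:
            scan_points = _varpro_scan(data, config)
        for p_try in scan_points:
            p2, v2, ok2 = _local_solve(residual, p_try, config)
            if v2 < entry[1]:
                entry = (p2, v2, entry[2] or ok2)
            if entry[1] < 1e-9:
                break
    if entry[1] >= 1e-9:
        for p_try in _restart_ladder(entry[0]):
            p2, v2, ok2 = _local_solve(residual, p_try, config)
            if v2 < entry[1]:
                entry = (p2, v2, entry[2] or ok2)
            if entry[1] < 1e-9:
                break
    if shared is not None:
        shared["refined"][key] = entry
    return entry


def single_fit(
    data: ObservationSeries,
    start: RateParameters,
    config: FitConfig | None = None,
    _shared: dict | None = None,
) -> tuple[RateParameters, float, bool]:
    """One robust local minimization of V from ``start``.

    Three deterministic stages: (1) a trust-region least-squares descent
    in log-rates (the residual structure of V makes Gauss–Newton steps far
    more effective than generic quasi-Newton here); if that stalls above
    rounding level, (2) a coarse variable-projection scan of the shape
    rates (:func:`_varpro_scan`) followed by fresh descents, and (3) the
    restart ladder redistributing the diffusion/convection split
    (:func:`_restart_ladder`).  The best point wins.  Optimizer failures
    are reported through the convergence flag, never raised.
    """
    config = config or FitConfig()
    residual, n_extra = _residual_factory(data, config)
    p0 = np.clip(start.as_array(), *config.rate_bounds)
    if n_extra:
        scale = max(float(np.max(np.abs(data.values))), 1e-6)
        p0 = np.concatenate([p0, [1e-3 * scale, 1e-3 * scale]])
    try:
        p_best, v_best, ok = _local_solve(residual, p0, config)
        # refine only when the descent stalled above the best level this
        # dataset is known to reach (rounding level when running standalone)
        if _shared is not None:
            stalled = v_best > _shared["best_v"] * 1.01 + 1e-9
        else:
            stalled = v_best >= 1e-9
        if stalled:
            p_best, v_best, ok = _refine(
                residual, data, config, p_best, v_best, ok, _shared
            )
        if _shared is not None and v_best < _shared["best_v"]:
            _shared["best_v"] = v_best
        params = RateParameters.from_array(p_best[:4])
        return params, v_best, ok
    except (ValueError, np.linalg.LinAlgError) as exc:
        if "identically zero" in str(exc):
            raise
        return start, float(np.linalg.norm(residual(p0))), False


def multistart_fit(
    data: ObservationSeries, config: FitConfig | None = None
) -> FitResult:
    """Seeded multi-start calibration (200 log-uniform starts by default).

    The best point is the smallest final objective; exact ties go to the
    earliest start index.  Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = np.log(config.start_bounds[0]), np.log(config.start_bounds[1])
    starts = np.exp(rng.uniform(lo, hi, size=(config.n_starts, 4)))
    per_v = np.full(config.n_starts, np.inf)
    flags = np.zeros(config.n_starts, dtype=bool)
    best: RateParameters | None = None
    best_v = np.inf
    shared: dict = {"scan": None, "refined": {}, "best_v": np.inf}
    for i in range(config.n_starts):
        k, v, ok = single_fit(
            data, RateParameters.from_array(starts[i]), config, _shared=shared
        )
        per_v[i] = v
        flags[i] = ok
        if ok and v < best_v:
            best, best_v = k, v
    if best is None:
        raise RuntimeError(
            f"all {config.n_starts} optimization starts failed to converge "
            f"(final objectives: min {np.min(per_v):.3e})"
        )
    frac = float(np.mean(per_v[flags] <= best_v + 1e-6)) if flags.any() else 0.0
    yc = model_observable(best, data.times, mode=config.mode)
    fitted = ObservationSeries(
        times=data.times,
        values=yc,
        unit=data.unit,
        replicate=data.replicate,
        scenario_id=data.scenario_id,
    )
    return FitResult(
        params=best,
        v_min=best_v,
        per_start_v=per_v,
        converged=flags,
        fraction_at_minimum=frac,
        seed=config.seed,
        fitted=fitted,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Simulation-study summary of how well the rates are re-estimated."""

    truth: RateParameters
    estimates: pd.DataFrame  # columns k_in,k_d,k_c,k_out,V_min per repeat
    noise_cv: float
    n_failed: int

    @property
    def relative_errors(self) -> pd.DataFrame:
        t = self.truth.as_array()
        cols = ["k_in", "k_d", "k_c", "k_out"]
        return (self.estimates[cols] - t) / t

    def summary(self) -> pd.DataFrame:
        rel = self.relative_errors.abs()
        return pd.DataFrame(
            {
                "median_abs_rel_error": rel.median(),
                "bias": self.relative_errors.mean(),
                "rmse": np.sqrt((self.relative_errors**2).mean()),
            }
        )


#: Reference truth for recovery studies: convection-dominated transport
#: (unique observational equivalence class) with cascade and outflow
#: timescales both resolvable on the long-exposure chip grid.
RECOVERY_REFERENCE_TRUTH = RateParameters(k_in=10.0, k_d=0.05, k_c=2.0, k_out=0.5)


def add_sampling_noise(
    y: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample multiplicative noise on the *collected increments*.

    Each timed perfusate sample is an independently collected and measured
    aliquot, so measurement error multiplies the per-interval increment;
    the cumulative series is their running sum (negative increments are
    clipped, keeping the series monotone like the real curves).
    """
    inc = np.diff(y, prepend=0.0)
    inc = np.clip(inc * (1.0 + cv * rng.standard_normal(inc.size)), 0.0, None)
    return np.cumsum(inc)


def parameter_recovery_experiment(
    truth: RateParameters = RECOVERY_REFERENCE_TRUTH,
    times: Sequence[float] | None = None,
    noise_cv: float = 0.10,
    n_repeats: int = 20,
    seed: int = 0,
    n_replicates: int = 3,
    config: FitConfig | None = None,
) -> RecoveryReport:
    """Simulate → perturb → refit, ``n_repeats`` times.

    Each repeat draws ``n_replicates`` noisy replicates (per-sample
    multiplicative noise on the collected increments, see
    :func:`add_sampling_noise`) and fits their mean curve — the object the
    chip study itself analyses.  Note the recovery of all four rates is
    only meaningful where the truth has a unique observational equivalence
    class (see the identifiability module); k_in and k_out are the
    practically best-determined rates on monotone cumulative data, while
    the diffusion/convection split is sloppy.
    """
    if n_repeats < 0:
        raise ValueError("n_repeats must be >= 0")
    # default grid: the 12 h / 30 min long-exposure sampling design, the
    # most informative of the chip schedules for the outflow rate
    t = np.linspace(0.0, 12.0, 25) if times is None else np.asarray(times, dtype=float)
    config = config or FitConfig(n_starts=16)
    rng = np.random.default_rng(seed)
    y0 = model_observable(truth, t, mode=config.mode)
    rows = []
    n_failed = 0
    for rep in range(n_repeats):
        if noise_cv:
            y = np.mean(
                [add_sampling_noise(y0, noise_cv, rng) for _ in range(n_replicates)],
                axis=0,
            )
        else:
            y = y0
        series = ObservationSeries(times=t, values=y, replicate=rep)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = multistart_fit(
                series,
                replace(config, seed=sub_seed),
            )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        k = fit.params
        rows.append(
            {
                "repeat": rep,
                "k_in": k.k_in,
                "k_d": k.k_d,
                "k_c": k.k_c,
                "k_out": k.k_out,
                "V_min": fit.v_min,
            }
        )
    estimates = pd.DataFrame(
        rows, columns=["repeat", "k_in", "k_d", "k_c", "k_out", "V_min"]
    )
    return RecoveryReport(
        truth=truth, estimates=estimates, noise_cv=noise_cv, n_failed=n_failed
    )


@dataclass(frozen=True)
class TwoPhaseFit:
    """Continuous two-segment linear description of a penetration curve."""

    breakpoint: float
    slope_slow: float
    slope_rapid: float
    intercept_slow: float
    intercept_rapid: float
    rss: float

    def predict(self, times: Sequence[float]) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return np.where(
            t <= self.breakpoint,
            self.intercept_slow + self.slope_slow * t,
            self.intercept_rapid + self.slope_rapid * t,
        )


def two_phase_regression(data: ObservationSeries) -> TwoPhaseFit:
    """Best continuous piecewise-linear fit with one breakpoint.

    Candidate breakpoints are the observed interior sample times with at
    least three points on each side; for each candidate the hinge model
    y = β0 + β1·t + β2·(t − t_b)₊ is solved by least squares (continuity
    at the breakpoint is built into the hinge), and the candidate with the
    smallest residual sum of squares wins.
    """
    t, y = data.times, data.values
    if t.size < 6:
        raise ValueError(f"two-phase regression needs >= 6 samples, got {t.size}")
    best: TwoPhaseFit | None = None
    for j in range(t.size):
        tb = t[j]
        if np.sum(t <= tb) < 3 or np.sum(t > tb) < 3:
            continue
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ beta - y) ** 2))
        if best is None or rss < best.rss - 1e-15 * max(best.rss, 1.0):
            b0, b1, b2 = beta
            best = TwoPhaseFit(
                breakpoint=float(tb),
                slope_slow=float(b1),
                slope_rapid=float(b1 + b2),
                intercept_slow=float(b0),
                intercept_rapid=float(b0 - b2 * tb),
                rss=rss,
            )
    if best is None:
        raise ValueError("no admissible breakpoint with >= 3 points per segment")
    return best
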