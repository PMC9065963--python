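"""Time integration of the coupled population / service fields.

The nonlocal terms make the semi-discrete system non-stiff at the default
rates (every relaxation rate is at most a few per year), so the default
integrator is an embedded explicit Runge-Kutta pair (SciPy's RK45) with
relative tolerance 1e-6. A fixed-step classical RK4 mode is provided as a
cross-check. Parameters may follow a piecewise-linear schedule in time,
which is how slowly changing travel behaviour (widening kernels) can be
explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import ModelParams, RhsEvaluator, sigma
from .errors import ConfigError, IntegrationError
from .grids import ScalarField, SpatialGrid
from .kernels import convolve_periodic
from .synthetic_fields import FieldSpec, generate

__all__ = [
    "SimulationConfig",
    "StateHistory",
    "ParameterSchedule",
    "integrate",
    "scenario_emergence",
    "scenario_metastable",
    "scenario_growth_2d",
]

# parameters that change the cached kernel transforms when scheduled
_KERNEL_PARAMS = ("beta_s", "beta_p1", "beta_p2", "a_p")
_SCHEDULABLE = _KERNEL_PARAMS + ("D", "f", "g", "lam", "mu", "alpha1", "r", "c", "alpha2")
# how far (relative) an integrator overshoot may leave the admissible set
# before it is treated as a blow-up rather than round-off
_OVERSHOOT_TOL = 1e-9


@dataclass(frozen=True)
class ParameterSchedule:
    """Piecewise-linear time profiles for a subset of model parameters.

    ``profiles`` maps a parameter name to a sequence of ``(time, value)``
    breakpoints; values are held constant outside the breakpoint range.
    """

    profiles: dict

    def __post_init__(self) -> None:
        for name, pts in self.profiles.items():
            if name not in _SCHEDULABLE:
                raise ConfigError(f"cannot schedule unknown parameter {name!r}")
            pts = sorted((float(t), float(v)) for t, v in pts)
            if len(pts) < 1:
                raise ConfigError(f"empty schedule for {name!r}")
            self.profiles[name] = pts

    def touches_kernels(self) -> bool:
        return any(name in _KERNEL_PARAMS for name in self.profiles)

    def params_at(self, params: ModelParams, t: float) -> ModelParams:
        overrides = {}
        for name, pts in self.profiles.items():
            ts = [q[0] for q in pts]
            vs = [q[1] for q in pts]
            overrides[name] = float(np.interp(t, ts, vs))
        return replace(params, **overrides)


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    grid: SpatialGrid
    params: ModelParams
    t_end: float
    output_interval: float = 10.0
    initial_p: ScalarField | FieldSpec | None = None
    initial_s: ScalarField | None = None
    schedule: ParameterSchedule | None = None
    method: str = "rk45"  # "rk45" (adaptive) or "rk4" (fixed step)
    rtol: float = 1e-6
    atol_p: float = 1e-3
    atol_s: float = 1e-8
    dt: float = 0.01  # fixed step for method="rk4", years

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ConfigError("t_end must be positive")
        if self.method not in ("rk45", "rk4"):
            raise ConfigError(f"unknown integrator {self.method!r}")
        if self.initial_p is None:
            raise ConfigError("an initial population field is required")


@dataclass
class StateHistory:
    """Snapshots of (p, s) at the requested output times."""

    times: np.ndarray
    p: list  # list of arrays on the grid
    s: list
    grid: SpatialGrid
    params: ModelParams
    mass: np.ndarray = field(default=None)  # mean population per snapshot

    def __post_init__(self) -> None:
        if self.mass is None:
            self.mass = np.array([float(np.mean(pi)) for pi in self.p])

    def field_p(self, i: int = -1) -> ScalarField:
        return ScalarField(self.grid, self.p[i], role="population")

    def field_s(self, i: int = -1) -> ScalarField:
        return ScalarField(self.grid, self.s[i], role="service")

    def mass_drift(self) -> float:
        """Largest relative change of mean population over the run."""
        m0 = self.mass[0]
        return float(np.max(np.abs(self.mass - m0)) / abs(m0)) if m0 else 0.0


def _resolve_initial(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    ip = config.initial_p
    if isinstance(ip, FieldSpec):
        p_field = generate(ip, config.grid)
    elif isinstance(ip, ScalarField):
        p_field = ip
    else:
        raise ConfigError("initial_p must be a ScalarField or FieldSpec")
    if p_field.grid != config.grid:
        raise ConfigError("initial field grid differs from configured grid")
    p0 = np.array(p_field.values, dtype=float)
    if config.initial_s is None:
        # default: services at their carrying capacity for the initial layout
        P = convolve_periodic(p_field, config.params.w_s(config.grid.dimension))
        s0 = np.asarray(sigma(np.maximum(P.values, 0.0), config.params))
        if config.params.variant in ("competition", "growth"):
            s0 = np.maximum(s0 - config.params.alpha1 * p0, 0.0)
    else:
        if config.initial_s.grid != config.grid:
            raise ConfigError("initial_s grid differs from configured grid")
        s0 = np.array(config.initial_s.values, dtype=float)
    return p0, s0


class _Rhs:
    """Flattened RHS with kernel-transform caching across calls."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.grid = config.grid
        self.n = config.grid.n_cells
        self.schedule = config.schedule
        self._static = RhsEvaluator(self.grid, config.params)
        self._rebuild_kernels = bool(self.schedule and self.schedule.touches_kernels())

    def _evaluator(self, t: float) -> RhsEvaluator:
        if self.schedule is None:
            return self._static
        params_t = self.schedule.params_at(self.config.params, t)
        if self._rebuild_kernels:
            return RhsEvaluator(self.grid, params_t)
        ev = self._static
        if params_t != ev.params:
            # reuse cached transforms, swap the pointwise rates
            new = object.__new__(RhsEvaluator)
            new.grid = ev.grid
            new.params = params_t
            new._hat_p1, new._hat_p2, new._hat_s = ev._hat_p1, ev._hat_p2, ev._hat_s
            new._axes = ev._axes
            return new
        return ev

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        # no clipping here: near p = 0 and s = 0 the raw dynamics restore
        # the bounds, and clipping would remove that restoring term
        shape = self.grid.shape
        p = y[: self.n].reshape(shape)
        s = y[self.n :].reshape(shape)
        ev = self._evaluator(t)
        dp, ds = ev.both(p, s)
        return np.concatenate([dp.ravel(), ds.ravel()])


def _validate_snapshot(
    p: np.ndarray, s: np.ndarray, t: float, s_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(s))):
        raise IntegrationError(f"non-finite state at t = {t:g}")
    p_scale = max(1.0, float(np.max(np.abs(p))))
    if np.min(p) < -_OVERSHOOT_TOL * p_scale:
        raise IntegrationError(f"population went negative at t = {t:g}")
    # the innovation gate makes the service equation only piecewise smooth
    # at s = 0, so overshoot there is bounded by the solver tolerance, not
    # by machine precision
    if np.min(s) < -s_tol or np.max(s) > 1.0 + s_tol:
        raise IntegrationError(f"service fraction left [0, 1] at t = {t:g}")
    return np.maximum(p, 0.0), np.clip(s, 0.0, 1.0)


def integrate(config: SimulationConfig) -> StateHistory:
    """Advance the configured variant from t = 0 to ``t_end``.

    Output snapshots are produced every ``output_interval`` years (always
    including both endpoints). State invariants are enforced: round-off level
    overshoot is clipped, anything larger raises ``IntegrationError``.
    """
    p0, s0 = _resolve_initial(config)
    rhs = _Rhs(config)
    n = config.grid.n_cells
    y0 = np.concatenate([p0.ravel(), s0.ravel()])
    times = np.arange(0.0, config.t_end + 1e-9, config.output_interval)
    if times[-1] < config.t_end:
        times = np.append(times, config.t_end)

    if config.method == "rk45":
        atol = np.concatenate(
            [np.full(n, config.atol_p), np.full(n, config.atol_s)]
        )
        sol = solve_ivp(
            rhs,
            (0.0, config.t_end),
            y0,
            method="RK45",
            t_eval=times,
            rtol=config.rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}")
        ys = sol.y.T
        times = sol.t
    else:
        ys = [y0]
        y = y0.copy()
        t = 0.0
        next_out = 1
        dt = config.dt
        n_steps = int(np.ceil(config.t_end / dt))
        for step in range(n_steps):
            h = min(dt, config.t_end - t)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            while next_out < len(times) and t >= times[next_out] - 1e-9:
                ys.append(y.copy())
                next_out += 1
        ys = np.array(ys)
        times = times[: len(ys)]

    ps, ss = [], []
    s_tol = max(_OVERSHOOT_TOL, 1e4 * config.atol_s)
    for t, y in zip(times, ys):
        p, s = _validate_snapshot(
            y[:n].reshape(config.grid.shape), y[n:].reshape(config.grid.shape), t, s_tol
        )
        ps.append(p)
        ss.append(s)
    return StateHistory(np.asarray(times), ps, ss, config.grid, config.params)


# ---- named scenarios ---------------------------------------------------

def scenario_emergence(
    seed: int,
    points: int = 256,
    extent: float = 300.0,
    t_end: float = 150.0,
    dimension: int = 2,
    mean: float = 8000.0,
    sd: float = 1000.0,
    params: ModelParams | None = None,
    output_interval: float = 50.0,
) -> StateHistory:
    """City emergence from i.i.d. noise, ``p = mean + sd * N(0, 1)``.

    Base model at table defaults on a periodic box; services start at the
    carrying capacity of the initial population layout. After ~100-150 years
    distinct high-density clusters separated by ~50 km appear.
    """
    if params is None:
        params = ModelParams.defaults("base")
    grid = SpatialGrid.square(extent, points) if dimension == 2 else SpatialGrid.line(extent, points)
    spec = FieldSpec("noise", dict(mean=mean, sd=sd), seed=seed)
    cfg = SimulationConfig(
        grid=grid, params=params, t_end=t_end, output_interval=output_interval,
        initial_p=spec,
    )
    return integrate(cfg)


def scenario_metastable(
    t_end: float = 300.0,
    points: int = 512,
    long_run: bool = False,
) -> StateHistory:
    """Seven-bump metastable state on a 200 km interval.

    Starts from ``p(x, 0) = 10000 + 5000 cos(7 pi x / 100)`` (seven full
    periods on 200 km) with ``s(x, 0) = sigma(p(x, 0))``. The seven-bump
    state persists for centuries; coarsening to fewer bumps happens only on
    millennial timescales, so the default run is short and ``long_run=True``
    extends it tenfold.
    """
    params = ModelParams.defaults("base")
    grid = SpatialGrid.line(200.0, points)
    x = grid.axes()[0]
    p0 = 10000.0 + 5000.0 * np.cos(7.0 * np.pi * x / 100.0)
    s0 = np.asarray(sigma(p0, params))
    cfg = SimulationConfig(
        grid=grid,
        params=params,
        t_end=t_end * (10 if long_run else 1),
        output_interval=max(t_end / 6.0, 1.0),
        initial_p=ScalarField(grid, p0, role="population"),
        initial_s=ScalarField(grid, s0, role="service"),
    )
    return integrate(cfg)


def scenario_growth_2d(
    seed: int,
    points: int = 128,
    extent: float = 128.0,
    t_end: float = 400.0,
    seed_density: float = 200.0,
    occupied_fraction: float = 0.1,
    params: ModelParams | None = None,
    output_interval: float = 50.0,
) -> StateHistory:
    """Growth model: sparse settlement seeds grow into patterned cities.

    ``p0 = seed_density`` on a seeded random 10% of grid cells, zero
    elsewhere. Population first grows quasi-uniformly under the logistic
    term, then long-wavelength clusters condense, and finally short-
    wavelength out-of-phase service/population structure develops inside
    them.
    """
    if params is None:
        params = ModelParams.defaults("growth")
    grid = SpatialGrid.square(extent, points)
    spec = FieldSpec(
        "random_patches",
        dict(value=seed_density, fraction=occupied_fraction),
        seed=seed,
    )
    # tight service tolerance: s hugs its lower bound for decades here and
    # the innovation gate kinks the vector field at s = 0
    cfg = SimulationConfig(
        grid=grid, params=params, t_end=t_end, output_interval=output_interval,
        initial_p=spec, atol_s=1e-10,
    )
    return integrate(cfg)
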