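"""Right-hand sides of the coupled population / service model.

State variables on a periodic grid:

* ``p(x, t)`` — residential population density, persons/km^2;
* ``s(x, t)`` — fraction of land occupied by services, in [0, 1].

Three nested variants share the movement operator

.. math:: \\partial_t p = D \\int [A(x) p(y) - A(y) p(x)]\\, w_{p2}(x-y)\\,dy,

where the attractiveness ``A = (w_{p1} * s)(1 - s)`` couples population to
nearby services while penalising locally service-saturated land. The service
equation relaxes ``s`` towards a carrying capacity
``sigma(P) = 1 - exp(-(P/lambda)^mu)`` of the nonlocally weighted population
``P = w_s * p``:

* ``base``        — ``ds/dt = (f + g s)(sigma(P) - s)``; conserves total
  population.
* ``competition`` — services also compete with residents for space:
  ``ds/dt = (H(sigma(P) - (s + alpha1 p)) f + g s)(sigma(P) - (s + alpha1 p))``
  with Heaviside gate ``H`` shutting off innovation when there is no excess
  demand (convention ``H(x) = 1`` iff ``x > 0``); still conserves population.
* ``growth``      — adds logistic population growth
  ``r p (1 - (p + alpha2 s)/c)`` with services taking up carrying capacity.

Rates are per year; all kernels act through spectral periodic convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .errors import InvariantViolationError, ParameterError
from .grids import ScalarField, SpatialGrid
from .kernels import KernelSpec, check_grid_for_kernel, kernel_hat_grid

__all__ = [
    "ModelParams",
    "VARIANTS",
    "sigma",
    "sigma_prime",
    "attractiveness",
    "movement_rhs",
    "service_rhs",
    "population_rhs",
    "RhsEvaluator",
]

VARIANTS = ("base", "competition", "growth")

# Table-default rates and scales (persons, km, years)
_DEFAULTS = dict(
    D=2.0,        # movement rate, 1/yr
    f=0.05,       # service innovator rate, 1/yr
    g=2.0,        # service imitator rate, 1/yr
    lam=20000.0,  # population scale of sigma, persons/km^2
    mu=3.0,       # sigma steepness (dimensionless)
    beta_s=5.0,   # kernel scale of w_s, km
    beta_p1=1.0,  # kernel scale of w_p1, km
    beta_p2=10.0, # kernel scale of w_p2, km
    a_p=1.5,      # preferred distance to services, km
    alpha1=1.5e-5,  # space competition, km^2/person
    r=0.05,       # intrinsic growth rate, 1/yr
    c=12000.0,    # population carrying capacity, persons/km^2
    alpha2=1e5,   # service->population competition, persons/km^2
)


@dataclass(frozen=True)
class ModelParams:
    """All model parameters plus the variant tag.

    The ``base`` variant has no space competition and no preferred offset, so
    it forces ``a_p = 0`` and ``alpha1 = 0``; passing non-zero values with
    ``variant="base"`` is an error. ``mu >= 1`` is required: for ``mu < 1``
    the slope of the carrying capacity diverges at zero population and the
    linear analysis breaks down.
    """

    variant: str = "base"
    D: float = _DEFAULTS["D"]
    f: float = _DEFAULTS["f"]
    g: float = _DEFAULTS["g"]
    lam: float = _DEFAULTS["lam"]
    mu: float = _DEFAULTS["mu"]
    beta_s: float = _DEFAULTS["beta_s"]
    beta_p1: float = _DEFAULTS["beta_p1"]
    beta_p2: float = _DEFAULTS["beta_p2"]
    a_p: float = 0.0
    alpha1: float = 0.0
    r: float = _DEFAULTS["r"]
    c: float = _DEFAULTS["c"]
    alpha2: float = _DEFAULTS["alpha2"]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}")
        for name in ("D", "f", "g", "lam", "beta_s", "beta_p1", "beta_p2"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"parameter {name} must be positive")
        if self.mu < 1.0:
            raise ParameterError("mu must be >= 1")
        if self.a_p < 0 or self.alpha1 < 0:
            raise ParameterError("a_p and alpha1 must be non-negative")
        if self.variant == "base" and (self.a_p != 0.0 or self.alpha1 != 0.0):
            raise ParameterError("base variant requires a_p = 0 and alpha1 = 0")
        if self.variant == "growth":
            if not (self.r > 0 and self.c > 0 and self.alpha2 >= 0):
                raise ParameterError("growth variant needs r > 0, c > 0, alpha2 >= 0")

    @classmethod
    def defaults(cls, variant: str = "base", **overrides) -> "ModelParams":
        """Table-default parameter set for a variant."""
        if variant not in VARIANTS:
            raise ParameterError(f"unknown variant {variant!r}")
        kw = dict(_DEFAULTS)
        if variant == "base":
            kw["a_p"] = 0.0
            kw["alpha1"] = 0.0
        kw.update(overrides)
        return cls(variant=variant, **kw)

    def with_overrides(self, **overrides) -> "ModelParams":
        return replace(self, **overrides)

    # ---- kernels ------------------------------------------------------
    def w_p1(self, dimension: int = 1) -> KernelSpec:
        """Attraction kernel; shifted pair when a preferred offset is set."""
        if self.a_p > 0:
            return KernelSpec("shifted_sum", self.beta_p1, self.a_p, dimension)
        return KernelSpec("gaussian", self.beta_p1, 0.0, dimension)

    def w_p2(self, dimension: int = 1) -> KernelSpec:
        return KernelSpec("gaussian", self.beta_p2, 0.0, dimension)

    def w_s(self, dimension: int = 1) -> KernelSpec:
        return KernelSpec("gaussian", self.beta_s, 0.0, dimension)

    def kernel_specs(self, dimension: int = 1) -> tuple[KernelSpec, ...]:
        return (self.w_p1(dimension), self.w_p2(dimension), self.w_s(dimension))


# ---- pointwise nonlinearities -----------------------------------------

def sigma(P, params: ModelParams):
    """Service carrying capacity ``sigma(P) = 1 - exp(-(P/lambda)^mu)``.

    Maps nonlocal population ``P >= 0`` to the maximal supportable service
    land fraction in [0, 1); increasing, sigmoidal for ``mu > 1``.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ParameterError("sigma requires P >= 0")
    out = -np.expm1(-((P / params.lam) ** params.mu))
    return out if out.ndim else float(out)


def sigma_prime(p, params: ModelParams):
    """Slope of the carrying capacity, km^2/person.

    ``sigma'(p) = (mu/lambda) (p/lambda)^(mu-1) exp(-(p/lambda)^mu)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ParameterError("sigma_prime requires p >= 0")
    u = p / params.lam
    with np.errstate(divide="ignore"):
        out = (params.mu / params.lam) * u ** (params.mu - 1.0) * np.exp(-(u**params.mu))
    return out if out.ndim else float(out)


def _heaviside(x: np.ndarray) -> np.ndarray:
    """H(x) = 1 iff x > 0 (H(0) = 0 by convention)."""
    return (x > 0).astype(float)


# ---- cached spectral evaluator ----------------------------------------

class RhsEvaluator:
    """Evaluates model right-hand sides with cached kernel transforms.

    Precomputes the analytic kernel transforms on the grid's discrete
    wavenumbers once; every standard-format convolution is then two FFTs.
    """

    def __init__(self, grid: SpatialGrid, params: ModelParams):
        self.grid = grid
        self.params = params
        dim = grid.dimension
        for spec in params.kernel_specs(dim):
            check_grid_for_kernel(grid, spec)
        self._hat_p1 = kernel_hat_grid(params.w_p1(dim), grid)
        self._hat_p2 = kernel_hat_grid(params.w_p2(dim), grid)
        self._hat_s = kernel_hat_grid(params.w_s(dim), grid)
        self._axes = tuple(range(dim))

    def _conv(self, values: np.ndarray, what: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(
            np.fft.rfftn(values) * what, s=self.grid.shape, axes=self._axes
        )

    def attractiveness(self, s: np.ndarray) -> np.ndarray:
        return self._conv(s, self._hat_p1) * (1.0 - s)

    def movement(self, p: np.ndarray, s: np.ndarray) -> np.ndarray:
        A = self.attractiveness(s)
        return self.params.D * (
            A * self._conv(p, self._hat_p2) - p * self._conv(A, self._hat_p2)
        )

    def population(self, p: np.ndarray, s: np.ndarray) -> np.ndarray:
        out = self.movement(p, s)
        if self.params.variant == "growth":
            pr = self.params
            out = out + pr.r * p * (1.0 - (p + pr.alpha2 * s) / pr.c)
        return out

    def service(self, p: np.ndarray, s: np.ndarray) -> np.ndarray:
        pr = self.params
        # spectral ringing can push P fractionally below zero on sharp fields
        P = np.maximum(self._conv(p, self._hat_s), 0.0)
        sig = sigma(P, pr)
        if pr.variant == "base":
            return (pr.f + pr.g * s) * (sig - s)
        deficit = sig - (s + pr.alpha1 * p)
        return (_heaviside(deficit) * pr.f + pr.g * s) * deficit

    def both(self, p: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.population(p, s), self.service(p, s)


# ---- public field-level operations ------------------------------------

def _check_pair(p: ScalarField, s: ScalarField) -> None:
    p.same_grid(s)
    if np.any(s.values < -1e-9) or np.any(s.values > 1.0 + 1e-9):
        raise InvariantViolationError("service fraction outside [0, 1]")
    if np.any(p.values < -1e-9 * max(1.0, float(np.max(np.abs(p.values))))):
        raise InvariantViolationError("population field has negative values")


def attractiveness(s: ScalarField, params: ModelParams) -> ScalarField:
    """Attractiveness ``A = (w_p1 * s)(1 - s)`` of each location."""
    if np.any(s.values < -1e-9) or np.any(s.values > 1.0 + 1e-9):
        raise InvariantViolationError("service fraction outside [0, 1]")
    ev = RhsEvaluator(s.grid, params)
    return ScalarField(s.grid, ev.attractiveness(s.values))


def movement_rhs(p: ScalarField, s: ScalarField, params: ModelParams) -> ScalarField:
    """Population redistribution rate; integrates to zero by antisymmetry."""
    _check_pair(p, s)
    ev = RhsEvaluator(p.grid, params)
    return ScalarField(p.grid, ev.movement(p.values, s.values))


def service_rhs(p: ScalarField, s: ScalarField, params: ModelParams) -> ScalarField:
    """Service land-fraction rate of change (1/yr) for the active variant."""
    _check_pair(p, s)
    ev = RhsEvaluator(p.grid, params)
    return ScalarField(p.grid, ev.service(p.values, s.values))


def population_rhs(p: ScalarField, s: ScalarField, params: ModelParams) -> ScalarField:
    """Population rate of change: movement plus logistic growth if enabled."""
    _check_pair(p, s)
    ev = RhsEvaluator(p.grid, params)
    return ScalarField(p.grid, ev.population(p.values, s.values))
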