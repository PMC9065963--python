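"""Linear stability analysis of the homogeneous state.

A spatially uniform state ``(p0, s0)`` perturbed by a single Fourier mode
``e^{ikx}`` obeys a 2x2 linear system with matrix ``J(p0, s0, k)`` whose
entries involve the kernel transforms evaluated at the mode's wavenumber.
The sign of the leading eigenvalue's real part over ``k`` is the dispersion
relation: a positive band signals a Turing-type instability with a preferred
pattern wavelength ``2 pi / k*``. The eigenvector of the leading eigenvalue
says whether population and services grow together (in phase, the ~50 km
city-spacing mode) or apart (out of phase, the ~4-5 km within-city mode).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .dynamics import ModelParams, sigma, sigma_prime
from .errors import (
    NoSteadyStateError,
    NoWindowError,
    ParameterError,
    UnsupportedVariantError,
)
from .kernels import kernel_hat

__all__ = [
    "HomogeneousState",
    "DispersionRelation",
    "homogeneous_state",
    "linearization_at_k",
    "jacobian_at_k",
    "dispersion",
    "default_k_grid",
    "instability_condition",
    "critical_wavenumber",
    "bifurcation_point",
    "phase_diagram",
]

#: eigenvector components smaller than this (relative to the vector norm)
#: give a "neutral" phase label instead of a sign read off noise
_PHASE_COMPONENT_TOL = 1e-12


@dataclass(frozen=True)
class HomogeneousState:
    """Spatially uniform steady state of a model variant."""

    p0: float
    s0: float
    variant: str

    @property
    def services_extinct(self) -> bool:
        return self.s0 == 0.0 and self.variant in ("competition", "growth")


@dataclass
class DispersionRelation:
    """Leading growth rate and phase label per wavenumber.

    Attributes
    ----------
    k : array, rad/km
    growth_rate : array, 1/yr — max real part of the eigenvalues of J(k)
    phase : array of {"in_phase", "out_of_phase", "neutral", "oscillatory"}
    """

    k: np.ndarray
    growth_rate: np.ndarray
    phase: np.ndarray
    state: HomogeneousState

    def max_rate(self) -> float:
        return float(np.max(self.growth_rate))

    def dominant_mode(self) -> tuple[float, float, str] | None:
        """(k*, rate, label) of the fastest-growing mode, or None if stable.

        k* is refined by parabolic interpolation through the discrete
        maximum, so it is not restricted to the k grid.
        """
        i = int(np.argmax(self.growth_rate))
        if self.growth_rate[i] <= 0.0:
            return None
        k_star, rate = _parabolic_refine(self.k, self.growth_rate, i)
        return k_star, rate, str(self.phase[i])

    def unstable_bands(self) -> list[dict]:
        """Contiguous unstable k-intervals with their dominant mode."""
        unstable = self.growth_rate > 0.0
        bands: list[dict] = []
        i = 0
        n = len(self.k)
        while i < n:
            if not unstable[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and unstable[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            rates = self.growth_rate[seg]
            loc = i + int(np.argmax(rates))
            k_dom, rate_dom = _parabolic_refine(self.k, self.growth_rate, loc)
            bands.append(
                dict(
                    k_min=float(self.k[i]),
                    k_max=float(self.k[j]),
                    k_dominant=k_dom,
                    rate=rate_dom,
                    phase=str(self.phase[loc]),
                )
            )
            i = j + 1
        return bands


def _parabolic_refine(k: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through three points around index ``i``."""
    if i == 0 or i == len(k) - 1:
        return float(k[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(k[i]), float(y[i])
    # uniform-in-index parabola; k spacing assumed locally uniform
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    h = k[i + 1] - k[i] if delta >= 0 else k[i] - k[i - 1]
    k_star = float(k[i] + delta * h)
    y_star = float(y1 - 0.25 * (y0 - y2) * delta)
    return k_star, y_star


# ---- homogeneous states -----------------------------------------------

def homogeneous_state(params: ModelParams, pbar: float | None = None) -> HomogeneousState:
    """Spatially uniform steady state.

    ``base``: ``p0 = pbar``, ``s0 = sigma(p0)``.
    ``competition``: ``p0 = pbar``, ``s0 = max(0, sigma(p0) - alpha1 p0)``
    (services go extinct when space competition exceeds demand).
    ``growth``: ``pbar`` is ignored; ``p0`` solves
    ``p0 + alpha2 * max(0, sigma(p0) - alpha1 p0) = c``.
    """
    if params.variant in ("base", "competition"):
        if pbar is None or not pbar > 0:
            raise ParameterError("pbar must be positive for this variant")
        p0 = float(pbar)
        s_raw = sigma(p0, params) - params.alpha1 * p0
        s0 = s_raw if params.variant == "competition" else sigma(p0, params)
        return HomogeneousState(p0, max(0.0, float(s0)), params.variant)

    def resid(p: float) -> float:
        s = max(0.0, sigma(p, params) - params.alpha1 * p)
        return p + params.alpha2 * s - params.c

    lo, hi = 1e-8, params.c
    if resid(lo) > 0 or resid(hi) < 0:
        raise NoSteadyStateError("no homogeneous steady state in (0, c]")
    p0 = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-15)
    s0 = max(0.0, float(sigma(p0, params) - params.alpha1 * p0))
    return HomogeneousState(float(p0), s0, "growth")


# ---- per-mode linearization -------------------------------------------

def linearization_at_k(
    p0: float,
    s0: float,
    params: ModelParams,
    k: float,
    gate_open: bool | None = None,
) -> np.ndarray:
    """2x2 linearization of the model about a *general* uniform state.

    Valid at any spatially uniform ``(p0, s0)``, not only steady states; at a
    steady state it reduces to the stability matrix ``J(p0, s0, k)``. For the
    competition/growth service equation the Heaviside innovation gate makes
    the right-hand side one-sidedly differentiable where the supply-demand
    deficit is zero; ``gate_open`` selects the branch (default: open unless
    the deficit is strictly negative).
    """
    pr = params
    w1 = kernel_hat(pr.w_p1(), k)
    w2 = kernel_hat(pr.w_p2(), k)
    ws = kernel_hat(pr.w_s(), k)

    J11 = -pr.D * s0 * (1.0 - s0) * (1.0 - w2)
    J12 = pr.D * p0 * (1.0 - w2) * ((1.0 - s0) * w1 - s0)
    if pr.variant == "growth":
        bracket = 1.0 - (p0 + pr.alpha2 * s0) / pr.c
        J11 += pr.r * bracket - pr.r * p0 / pr.c
        J12 += -pr.r * pr.alpha2 * p0 / pr.c

    if pr.variant == "base":
        d0 = sigma(p0, pr) - s0
        J21 = (pr.f + pr.g * s0) * sigma_prime(p0, pr) * ws
        J22 = pr.g * d0 - (pr.f + pr.g * s0)
    else:
        d0 = sigma(p0, pr) - (s0 + pr.alpha1 * p0)
        if gate_open is None:
            gate_open = d0 >= 0.0
        slope = sigma_prime(p0, pr) * ws - pr.alpha1
        if gate_open:
            J21 = (pr.f + pr.g * s0) * slope
            J22 = pr.g * d0 - (pr.f + pr.g * s0)
        else:
            J21 = pr.g * s0 * slope
            J22 = pr.g * (d0 - s0)
    return np.array([[J11, J12], [J21, J22]], dtype=float)


def jacobian_at_k(state: HomogeneousState, params: ModelParams, k: float) -> np.ndarray:
    """Stability matrix ``J(p0, s0, k)`` at a homogeneous steady state.

    On the services-extinct branch (``s0 = 0`` with negative deficit) the
    innovation gate is shut, so the service row degenerates to pure decay.
    """
    if state.variant != params.variant:
        raise ParameterError("state and params variants differ")
    gate_open: bool | None = None
    if params.variant in ("competition", "growth") and state.s0 == 0.0:
        deficit = sigma(state.p0, params) - params.alpha1 * state.p0
        gate_open = deficit > 0.0
    return linearization_at_k(state.p0, state.s0, params, k, gate_open=gate_open)


def _leading_eig(J: np.ndarray) -> tuple[complex, np.ndarray]:
    vals, vecs = np.linalg.eig(J)
    i = int(np.argmax(vals.real))
    return vals[i], vecs[:, i]


def _phase_label(lam: complex, vec: np.ndarray) -> str:
    if abs(lam.imag) > 1e-12 * max(1.0, abs(lam.real)):
        return "oscillatory"
    v = vec.real
    nrm = np.linalg.norm(v)
    if nrm == 0.0 or np.min(np.abs(v)) / nrm < _PHASE_COMPONENT_TOL:
        return "neutral"
    return "in_phase" if v[0] * v[1] > 0 else "out_of_phase"


def default_k_grid(n: int = 512, k_max: float = 3.0) -> np.ndarray:
    """Wavenumber grid on (0, k_max] covering both in-phase (~0.1 rad/km)
    and out-of-phase (~1.2-1.6 rad/km) regimes."""
    return np.linspace(k_max / n, k_max, n)


def dispersion(
    params: ModelParams,
    pbar: float | None = None,
    k_grid: np.ndarray | None = None,
    state: HomogeneousState | None = None,
) -> DispersionRelation:
    """Dispersion relation Re lambda_+(k) with per-mode phase labels."""
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ParameterError("empty wavenumber grid")
    if np.any(k_grid <= 0) or np.any(np.diff(k_grid) <= 0):
        raise ParameterError("k grid must be positive and strictly increasing")
    if state is None:
        state = homogeneous_state(params, pbar)
    rates = np.empty_like(k_grid)
    labels = np.empty(k_grid.shape, dtype=object)
    for i, k in enumerate(k_grid):
        lam, vec = _leading_eig(jacobian_at_k(state, params, float(k)))
        rates[i] = lam.real
        labels[i] = _phase_label(lam, vec)
    return DispersionRelation(k_grid, rates, labels, state)


# ---- instability conditions and bifurcation ---------------------------

def instability_condition(params: ModelParams, pbar: float) -> bool:
    """Base model: unstable wavenumbers exist iff
    ``s0 (1 - s0) / (p0 sigma'(p0)) + s0 < 1 - s0``."""
    if params.variant != "base":
        raise UnsupportedVariantError("instability_condition applies to the base variant")
    st = homogeneous_state(params, pbar)
    p0, s0 = st.p0, st.s0
    return s0 * (1.0 - s0) / (p0 * sigma_prime(p0, params)) + s0 < 1.0 - s0


def _det_at_k(state: HomogeneousState, params: ModelParams, k: float) -> float:
    J = jacobian_at_k(state, params, k)
    return float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])


def critical_wavenumber(params: ModelParams, pbar: float, k_max: float = 10.0) -> float:
    """Upper edge k_c of the unstable window (0, k_c) of the base model.

    Found by bracketed root search on ``det J(k) = 0`` (the trace is negative
    for k > 0, so instability is equivalent to a negative determinant).
    """
    if not instability_condition(params, pbar):
        raise NoWindowError("homogeneous state is stable; no unstable window")
    st = homogeneous_state(params, pbar)
    ks = np.linspace(1e-6, k_max, 4000)
    dets = np.array([_det_at_k(st, params, float(k)) for k in ks])
    neg = np.where(dets < 0)[0]
    if neg.size == 0:
        raise NoWindowError("determinant never negative on the scan grid")
    i = int(neg[-1])
    if i + 1 >= len(ks):
        raise NoWindowError(f"unstable window extends beyond k = {k_max}")
    return float(
        brentq(lambda k: _det_at_k(st, params, k), ks[i], ks[i + 1], xtol=1e-12)
    )


def bifurcation_point(params: ModelParams) -> tuple[float, float]:
    """Pattern-forming bifurcation of the base model.

    Solves ``s0 = mu (2 s0 - 1) ln(1 - s0)`` for ``s0`` in (0, 1/2) by
    bracketed bisection, then inverts the carrying capacity to get
    ``p0 = lambda (-ln(1 - s0))^(1/mu)``. Requires ``mu > 1`` (at ``mu = 1``
    the root collapses to zero).
    """
    mu = params.mu
    if mu < 1.0:
        raise ParameterError("bifurcation point requires mu >= 1")
    if mu == 1.0:
        raise ParameterError("mu = 1 is degenerate: bifurcation point at s0 = 0")

    def f(s: float) -> float:
        return s - mu * (2.0 * s - 1.0) * np.log1p(-s)

    lo, hi = 1e-8, 0.5 - 1e-12
    if not (f(lo) < 0 < f(hi)):
        raise ParameterError("failed to bracket the bifurcation condition")
    s_star = float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
    p_star = params.lam * (-np.log1p(-s_star)) ** (1.0 / mu)
    return s_star, float(p_star)


def phase_diagram(
    params: ModelParams,
    pbar: float,
    alpha1_grid: np.ndarray,
    ap_grid: np.ndarray,
    k_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Instability phase map over (alpha1, a_p) for the competition model.

    Returns an object array of shape ``(len(alpha1_grid), len(ap_grid))``
    with labels ``stable``, ``in_phase``, ``out_of_phase``, ``oscillatory``
    or ``services_extinct`` (cells where ``sigma(p0) <= alpha1 p0``).
    """
    if params.variant != "competition":
        raise UnsupportedVariantError("phase_diagram applies to the competition variant")
    if k_grid is None:
        k_grid = default_k_grid()
    alpha1_grid = np.asarray(alpha1_grid, dtype=float)
    ap_grid = np.asarray(ap_grid, dtype=float)
    labels = np.empty((alpha1_grid.size, ap_grid.size), dtype=object)
    for i, a1 in enumerate(alpha1_grid):
        for j, ap in enumerate(ap_grid):
            pr = replace(params, alpha1=float(a1), a_p=float(ap))
            if sigma(pbar, pr) <= a1 * pbar:
                labels[i, j] = "services_extinct"
                continue
            rel = dispersion(pr, pbar, k_grid)
            dom = rel.dominant_mode()
            labels[i, j] = "stable" if dom is None else dom[2]
    return labels
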