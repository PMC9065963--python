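"""Spatial interaction kernels, their Fourier transforms and periodic convolution.

Two kernel families are used by the model:

* ``gaussian`` — an isotropic Gaussian of standard deviation ``beta`` km,
  normalised to unit mass:

  .. math:: G(x, \\beta) = \\frac{1}{\\beta\\sqrt{2\\pi}} e^{-x^2/2\\beta^2}
            \\quad(\\text{1-D}), \\qquad
            G(\\mathbf{x}, \\beta) = \\frac{1}{2\\pi\\beta^2}
            e^{-|\\mathbf{x}|^2/2\\beta^2} \\quad(\\text{2-D}).

* ``shifted_sum`` — the mean of Gaussians shifted off-centre by a preferred
  distance ``offset`` (a_p) km along each axis direction; in 1-D
  ``(G(x + a) + G(x - a)) / 2``, in 2-D the mean of the four axis shifts.
  This encodes a population preference to live *near but not on top of*
  service locations; its transform changes sign, which is what makes
  short-wavelength out-of-phase patterns possible.

Convolution on a periodic grid is spectral: the analytic transform is
evaluated at the discrete wavenumbers of the grid, so there is no truncation
of kernel tails, provided the domain is large enough for the periodic images
to be negligible (the ``extent >= 10 beta`` guard).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainSizeError, ParameterError
from .grids import ScalarField, SpatialGrid

__all__ = [
    "KernelSpec",
    "kernel_profile",
    "kernel_hat",
    "kernel_hat_grid",
    "convolve_periodic",
    "check_grid_for_kernel",
]

_FAMILIES = ("gaussian", "shifted_sum")
# extent / beta ratio below which periodic wrap-around of the kernel mass
# would exceed ~1e-6
_MIN_EXTENT_BETAS = 10.0


@dataclass(frozen=True)
class KernelSpec:
    """Specification of a spatial weight kernel.

    Parameters
    ----------
    family
        ``"gaussian"`` or ``"shifted_sum"``.
    beta
        Gaussian length scale in km; must be positive.
    offset
        Shift distance a >= 0 in km (``shifted_sum`` only).
    dimension
        1 or 2.
    """

    family: str
    beta: float
    offset: float = 0.0
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown kernel family {self.family!r}")
        if not self.beta > 0:
            raise ParameterError("kernel beta must be positive")
        if self.offset < 0:
            raise ParameterError("kernel offset must be non-negative")
        if self.family == "gaussian" and self.offset != 0.0:
            raise ParameterError("gaussian kernel takes no offset")
        if self.dimension not in (1, 2):
            raise ParameterError("kernel dimension must be 1 or 2")

    @property
    def support_scale(self) -> float:
        """Length scale controlling how much domain the kernel needs (km)."""
        return self.beta + self.offset


def _gauss(r2: np.ndarray, beta: float, dimension: int) -> np.ndarray:
    """Unit-mass Gaussian density as a function of squared distance."""
    norm = (beta * np.sqrt(2.0 * np.pi)) ** dimension
    return np.exp(-r2 / (2.0 * beta**2)) / norm


def kernel_profile(spec: KernelSpec, x) -> np.ndarray:
    """Evaluate the kernel density at displacement ``x``.

    For 1-D specs ``x`` is scalar or array of displacements (km); for 2-D
    specs ``x`` is array-like with the last axis of length 2. Returns
    km^-1 (1-D) or km^-2 (2-D).
    """
    x = np.asarray(x, dtype=float)
    if spec.dimension == 1:
        if spec.family == "gaussian":
            out = _gauss(x**2, spec.beta, 1)
        else:
            a = spec.offset
            out = 0.5 * (
                _gauss((x + a) ** 2, spec.beta, 1) + _gauss((x - a) ** 2, spec.beta, 1)
            )
        return out
    if x.shape[-1] != 2:
        raise ParameterError("2-D kernel needs displacement vectors of length 2")
    if spec.family == "gaussian":
        return _gauss(np.sum(x**2, axis=-1), spec.beta, 2)
    a = spec.offset
    shifts = np.array([[a, 0.0], [-a, 0.0], [0.0, a], [0.0, -a]])
    out = np.zeros(x.shape[:-1])
    for sh in shifts:
        out += _gauss(np.sum((x - sh) ** 2, axis=-1), spec.beta, 2)
    return out / 4.0


def kernel_hat(spec: KernelSpec, k) -> np.ndarray:
    """Analytic Fourier transform \\hat{w}(k) at angular wavenumber ``k``.

    ``k`` is the (scalar) wavenumber along a single axis in rad/km, the form
    used by the 1-D linear stability analysis. ``\\hat{w}(0) = 1`` (unit
    mass) and ``|\\hat{w}| <= 1`` for both families.
    """
    k = np.asarray(k, dtype=float)
    envelope = np.exp(-0.5 * (spec.beta * k) ** 2)
    if spec.family == "gaussian":
        return envelope
    return np.cos(spec.offset * k) * envelope


def kernel_hat_grid(spec: KernelSpec, grid: SpatialGrid) -> np.ndarray:
    """Transform values on the grid's discrete wavenumbers (rfft layout).

    For a 2-D ``shifted_sum`` kernel the transform is
    ``(cos(a kx) + cos(a ky)) / 2 * exp(-beta^2 |k|^2 / 2)`` (mean of the
    four axis shifts).
    """
    if spec.dimension != grid.dimension:
        raise ParameterError("kernel and grid dimension differ")
    kmesh = grid.rfft_wavenumber_mesh()
    k2 = sum(km**2 for km in kmesh)
    envelope = np.exp(-0.5 * spec.beta**2 * k2)
    if spec.family == "gaussian":
        return envelope
    a = spec.offset
    osc = sum(np.cos(a * km) for km in kmesh) / grid.dimension
    return osc * envelope


def check_grid_for_kernel(grid: SpatialGrid, spec: KernelSpec) -> None:
    """Raise :class:`DomainSizeError` if the periodic box is too small."""
    needed = _MIN_EXTENT_BETAS * spec.beta + 2.0 * spec.offset
    if grid.min_extent() < needed:
        raise DomainSizeError(
            f"grid extent {grid.min_extent():g} km < {needed:g} km required "
            f"for kernel beta={spec.beta:g}, offset={spec.offset:g}"
        )


def convolve_periodic(field: ScalarField, spec: KernelSpec) -> ScalarField:
    """Periodic convolution ``w * field`` via the analytic transform.

    Constant fields are fixed points (unit kernel mass) and the spatial mean
    is preserved exactly because ``\\hat{w}(0) = 1``.
    """
    grid = field.grid
    check_grid_for_kernel(grid, spec)
    what = kernel_hat_grid(spec, grid)
    fhat = np.fft.rfftn(field.values)
    axes = tuple(range(grid.dimension))
    out = np.fft.irfftn(fhat * what, s=grid.shape, axes=axes)
    return ScalarField(grid, out, role="derived")
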