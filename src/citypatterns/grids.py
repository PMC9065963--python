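"""Periodic spatial grids and scalar fields.

All lengths are kilometres, wavenumbers are angular (rad / km), population
density is persons / km^2 and the service variable is a dimensionless land
fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvariantViolationError, ParameterError

__all__ = ["SpatialGrid", "ScalarField"]

_MIN_POINTS = 8


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform periodic grid in one or two dimensions.

    Parameters
    ----------
    extent
        Physical length of each axis in km. The domain is the periodic box
        ``[0, extent)`` per axis.
    points
        Number of grid points per axis.
    """

    extent: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        extent = tuple(float(e) for e in np.atleast_1d(self.extent))
        points = tuple(int(n) for n in np.atleast_1d(self.points))
        object.__setattr__(self, "extent", extent)
        object.__setattr__(self, "points", points)
        if len(extent) != len(points):
            raise ParameterError("extent and points must have the same length")
        if len(extent) not in (1, 2):
            raise ParameterError("only 1-D and 2-D grids are supported")
        if any(e <= 0 for e in extent):
            raise ParameterError("grid extent must be positive")
        if any(n < _MIN_POINTS for n in points):
            raise ParameterError(f"need at least {_MIN_POINTS} points per axis")

    # ---- constructors -------------------------------------------------
    @classmethod
    def line(cls, extent: float, points: int) -> "SpatialGrid":
        """1-D periodic interval."""
        return cls((float(extent),), (int(points),))

    @classmethod
    def square(cls, extent: float, points: int) -> "SpatialGrid":
        """2-D periodic square box."""
        return cls((float(extent),) * 2, (int(points),) * 2)

    # ---- geometry -----------------------------------------------------
    @property
    def dimension(self) -> int:
        return len(self.extent)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(e / n for e, n in zip(self.extent, self.points))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.points

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.points))

    @property
    def cell_volume(self) -> float:
        """km (1-D) or km^2 (2-D) per grid cell."""
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, ...]:
        """Coordinate array along each axis (km), origin at index 0."""
        return tuple(
            np.arange(n) * d for n, d in zip(self.points, self.spacing)
        )

    def coords(self) -> tuple[np.ndarray, ...]:
        """Broadcastable coordinate arrays on the full grid."""
        return tuple(np.meshgrid(*self.axes(), indexing="ij"))

    def wavenumbers(self) -> tuple[np.ndarray, ...]:
        """Angular wavenumbers (rad / km) along each axis, FFT ordering."""
        return tuple(
            2.0 * np.pi * np.fft.fftfreq(n, d=d)
            for n, d in zip(self.points, self.spacing)
        )

    def rfft_wavenumber_mesh(self) -> tuple[np.ndarray, ...]:
        """Wavenumber mesh matching ``numpy.fft.rfftn`` output layout."""
        ks = list(self.wavenumbers())
        ks[-1] = 2.0 * np.pi * np.fft.rfftfreq(self.points[-1], d=self.spacing[-1])
        return tuple(np.meshgrid(*ks, indexing="ij"))

    def min_extent(self) -> float:
        return min(self.extent)

    def fundamental_wavenumber(self) -> float:
        """Smallest non-zero angular wavenumber resolved on the grid."""
        return 2.0 * np.pi / max(self.extent)


@dataclass
class ScalarField:
    """Scalar values on a :class:`SpatialGrid`.

    ``role`` is one of ``"population"`` (p, persons/km^2, must be >= 0),
    ``"service"`` (s, land fraction in [0, 1]) or ``"derived"`` (no bound
    checks).
    """

    grid: SpatialGrid
    values: np.ndarray
    role: str = "derived"
    meta: dict = field(default_factory=dict)

    _BOUND_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ("population", "service", "derived"):
            raise ParameterError(f"unknown field role {self.role!r}")
        self.check_bounds()

    def check_bounds(self) -> None:
        v = self.values
        if self.role == "population":
            scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))
            if np.min(v, initial=0.0) < -self._BOUND_TOL * scale:
                raise InvariantViolationError("population field has negative values")
        elif self.role == "service":
            if np.min(v, initial=0.0) < -self._BOUND_TOL or np.max(
                v, initial=0.0
            ) > 1.0 + self._BOUND_TOL:
                raise InvariantViolationError("service fraction outside [0, 1]")

    # ---- convenience --------------------------------------------------
    @classmethod
    def constant(
        cls, grid: SpatialGrid, value: float, role: str = "derived"
    ) -> "ScalarField":
        return cls(grid, np.full(grid.shape, float(value)), role=role)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def total(self) -> float:
        """Spatial integral of the field (value * km^dimension)."""
        return float(np.sum(self.values)) * self.grid.cell_volume

    def with_values(self, values: np.ndarray, role: str | None = None) -> "ScalarField":
        return ScalarField(self.grid, values, role=self.role if role is None else role)

    def same_grid(self, other: "ScalarField") -> None:
        if self.grid != other.grid:
            raise GridMismatchError("fields are defined on different grids")
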