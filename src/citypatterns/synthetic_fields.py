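"""Seeded generators for initial conditions and estimator fixtures.

These stand in for external gridded population data: every generator is
bit-reproducible given its seed, and each planted structure (noise floor,
cosine modes, a lattice of city-like bumps, random settlement patches) has a
known length scale so the estimators in :mod:`citypatterns.lengthscale` can
be validated by round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .grids import ScalarField, SpatialGrid

__all__ = ["FieldSpec", "PointSet", "generate", "lsoa_like_points"]

_GENERATORS = ("noise", "cosine_modes", "city_lattice", "random_patches")


@dataclass(frozen=True)
class PointSet:
    """Irregular 2-D sample points with attached values (persons/km^2)."""

    coords: np.ndarray  # (n, 2), km
    values: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ParameterError("coords must have shape (n, 2)")
        if values.shape != (coords.shape[0],):
            raise ParameterError("values must match the number of points")
        if coords.shape[0] < 3:
            raise ParameterError("need at least 3 points")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FieldSpec:
    """Named generator plus its parameters and seed."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in _GENERATORS:
            raise ParameterError(f"unknown generator {self.generator!r}")


def _snap_wavelength(wavelength: float, extent: float) -> tuple[float, int]:
    """Snap a wavelength to the nearest periodic harmonic of the extent."""
    if wavelength <= 0:
        raise ParameterError("wavelength must be positive")
    harmonic = max(1, round(extent / wavelength))
    snapped = extent / harmonic
    if abs(snapped - wavelength) > 1e-9 * extent:
        warnings.warn(
            f"wavelength {wavelength:g} km is not commensurate with the "
            f"{extent:g} km periodic extent; snapped to {snapped:g} km",
            stacklevel=3,
        )
    return snapped, harmonic


def generate(spec: FieldSpec, grid: SpatialGrid) -> ScalarField:
    """Generate a population field from a :class:`FieldSpec`.

    Generators
    ----------
    ``noise``: ``mean + sd * N(0, 1)`` i.i.d. per cell, negatives truncated
    at zero (the truncated fraction is recorded in ``field.meta``).
    ``cosine_modes``: ``mean + sum_i amp_i cos(2 pi x / L_i)`` along the
    first axis, with each wavelength snapped to a periodic harmonic.
    ``city_lattice``: Gaussian bumps on a regular lattice with the given
    spacing — a caricature of evenly spaced cities.
    ``random_patches``: ``value`` on a seeded random fraction of cells.
    """
    rng = np.random.default_rng(spec.seed)
    pr = dict(spec.params)
    name = spec.generator

    if name == "noise":
        mean = float(pr.pop("mean", 8000.0))
        sd = float(pr.pop("sd", 1000.0))
        values = mean + sd * rng.standard_normal(grid.shape)
        truncated = float(np.mean(values < 0.0))
        values = np.maximum(values, 0.0)
        out = ScalarField(grid, values, role="population")
        out.meta["truncated_fraction"] = truncated

    elif name == "cosine_modes":
        mean = float(pr.pop("mean", 10000.0))
        wavelengths = np.atleast_1d(pr.pop("wavelengths", pr.pop("wavelength", 50.0)))
        amplitudes = np.atleast_1d(pr.pop("amplitudes", pr.pop("amplitude", 1000.0)))
        if amplitudes.size == 1:
            amplitudes = np.full(wavelengths.shape, float(amplitudes[0]))
        if amplitudes.shape != wavelengths.shape:
            raise ParameterError("amplitudes and wavelengths must align")
        x = grid.coords()[0]
        values = np.full(grid.shape, mean)
        for L, amp in zip(wavelengths, amplitudes):
            snapped, _ = _snap_wavelength(float(L), grid.extent[0])
            values = values + float(amp) * np.cos(2.0 * np.pi * x / snapped)
        truncated = float(np.mean(values < 0.0))
        values = np.maximum(values, 0.0)
        out = ScalarField(grid, values, role="population")
        out.meta["truncated_fraction"] = truncated

    elif name == "city_lattice":
        spacing = float(pr.pop("spacing", 45.0))
        amplitude = float(pr.pop("amplitude", 5000.0))
        baseline = float(pr.pop("mean", 1000.0))
        # compact cities: wide bumps (>~ spacing/8) lose their harmonic
        # content and the radial correlogram peak drifts to the Bessel
        # position 1.117 x spacing
        width = float(pr.pop("width", spacing / 10.0))
        # seeded jitter (fraction of the spacing): a perfectly regular
        # lattice is anisotropic under radial binning; real city patterns
        # are disordered
        jitter = float(pr.pop("jitter", 0.1))
        snapped, n_cities = _snap_wavelength(spacing, grid.extent[0])
        values = np.full(grid.shape, baseline)
        centers_per_axis = [
            (np.arange(round(e / snapped)) + 0.5) * (e / round(e / snapped))
            for e in grid.extent
        ]
        centers = np.array(np.meshgrid(*centers_per_axis, indexing="ij")).reshape(
            grid.dimension, -1
        ).T
        centers = centers + rng.normal(scale=jitter * snapped, size=centers.shape)
        coords = grid.coords()
        for center in centers:
            r2 = np.zeros(grid.shape)
            for ax in range(grid.dimension):
                d = np.abs(coords[ax] - center[ax])
                d = np.minimum(d, grid.extent[ax] - d)  # periodic distance
                r2 = r2 + d**2
            values = values + amplitude * np.exp(-r2 / (2.0 * width**2))
        out = ScalarField(grid, values, role="population")
        out.meta["spacing_km"] = snapped

    elif name == "random_patches":
        value = float(pr.pop("value", 200.0))
        fraction = float(pr.pop("fraction", 0.1))
        if not 0.0 < fraction <= 1.0:
            raise ParameterError("patch fraction must be in (0, 1]")
        baseline = float(pr.pop("baseline", 0.0))
        n_cells = grid.n_cells
        n_occ = max(1, round(fraction * n_cells))
        idx = rng.choice(n_cells, size=n_occ, replace=False)
        values = np.full(n_cells, baseline)
        values[idx] = value
        out = ScalarField(grid, values.reshape(grid.shape), role="population")
        out.meta["occupied_fraction"] = n_occ / n_cells

    else:  # pragma: no cover - guarded by FieldSpec
        raise ParameterError(f"unknown generator {name!r}")

    if pr:
        raise ParameterError(f"unknown {name} parameters: {sorted(pr)}")
    return out


def lsoa_like_points(
    n: int,
    extent: float,
    clustering: float = 0.5,
    seed: int = 0,
    wavelength: float = 45.0,
    amplitude: float = 4000.0,
    mean: float = 5000.0,
    noise_sd: float = 500.0,
) -> PointSet:
    """Irregular census-like centroids with a planted spatial pattern.

    Point locations mix a uniform scatter with clumps around random centres
    (``clustering`` is the clumped fraction), mimicking irregular census
    output areas. Values are sampled from a planted city-like pattern —
    Gaussian density bumps on a lattice with the given spacing
    (``wavelength``) — plus observation noise, so the planted inter-city
    spacing can be recovered from the correlogram.
    """
    if n < 10:
        raise ParameterError("need at least 10 points")
    if not 0.0 <= clustering <= 1.0:
        raise ParameterError("clustering must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_clustered = int(round(clustering * n))
    pts = [rng.uniform(0.0, extent, size=(n - n_clustered, 2))]
    if n_clustered:
        n_centers = max(1, int(round(extent / max(wavelength, 1.0))) ** 2 // 2)
        centers = rng.uniform(0.0, extent, size=(n_centers, 2))
        which = rng.integers(0, n_centers, size=n_clustered)
        scatter = rng.normal(scale=extent / 30.0, size=(n_clustered, 2))
        pts.append(np.mod(centers[which] + scatter, extent))
    coords = np.concatenate(pts, axis=0)
    # planted pattern: Gaussian city bumps on a lattice of the given spacing
    per_axis = max(1, round(extent / wavelength))
    spacing = extent / per_axis
    city = (np.arange(per_axis) + 0.5) * spacing
    width = spacing / 10.0
    values = np.full(coords.shape[0], mean, dtype=float)
    for cx in city:
        for cy in city:
            dx = np.abs(coords[:, 0] - cx)
            dy = np.abs(coords[:, 1] - cy)
            dx = np.minimum(dx, extent - dx)
            dy = np.minimum(dy, extent - dy)
            values += amplitude * np.exp(-(dx**2 + dy**2) / (2.0 * width**2))
    values += rng.normal(scale=noise_sd, size=coords.shape[0])
    return PointSet(coords, np.maximum(values, 0.0))
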