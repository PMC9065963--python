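"""Moran correlograms and transect spectra on planted patterns."""

import numpy as np
import pytest

from citypatterns import (
    ScalarField,
    SpatialGrid,
    dominant_length_from_correlogram,
    moran_correlogram,
    transect_power_spectrum,
)
from citypatterns.errors import DegenerateInputError, ParameterError
from citypatterns.lengthscale import Correlogram
from citypatterns.synthetic_fields import PointSet


def _planted_cosine_field(wavelength, extent=180.0, points=180, noise_sd=0.0, seed=0):
    grid = SpatialGrid.square(extent, points)
    X, Y = grid.coords()
    k = 2 * np.pi / wavelength
    vals = 1000.0 + 400.0 * (np.cos(k * X) + np.cos(k * Y))
    if noise_sd:
        vals = vals + np.random.default_rng(seed).normal(scale=noise_sd, size=vals.shape)
    return ScalarField(grid, vals)


def _brute_force_moran_grid(field, bin_width, max_distance):
    """O(N^2) pair enumeration with periodic minimal-image distances."""
    grid = field.grid
    X, Y = grid.coords()
    coords = np.column_stack([X.ravel(), Y.ravel()])
    z = field.values.ravel() - field.values.mean()
    n = len(z)
    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        dx = np.abs(coords[:, 0] - coords[i, 0])
        dy = np.abs(coords[:, 1] - coords[i, 1])
        dx = np.minimum(dx, grid.extent[0] - dx)
        dy = np.minimum(dy, grid.extent[1] - dy)
        d = np.hypot(dx, dy)
        which = (d / bin_width).astype(int)
        ok = (d > 0) & (which < n_bins)
        np.add.at(sums, which[ok], z[i] * z[ok])
        np.add.at(counts, which[ok], 1)
    denom = np.sum(z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = np.where(counts > 0, n * sums / (counts * denom), np.nan)
    return I


class TestMoranGrid:
    def test_matches_brute_force_pair_enumeration(self):
        field = _planted_cosine_field(15.0, extent=48.0, points=16, noise_sd=100.0, seed=4)
        curve = moran_correlogram(field, bin_width=3.0)
        brute = _brute_force_moran_grid(field, 3.0, 24.0)
        np.testing.assert_allclose(curve.I, brute, atol=1e-10)

    def test_iid_noise_has_no_structure(self):
        grid = SpatialGrid.square(128.0, 64)
        vals = np.random.default_rng(8).normal(size=grid.shape)
        curve = moran_correlogram(ScalarField(grid, vals), bin_width=2.0)
        finite = np.isfinite(curve.I) & (curve.pair_count > 0)
        bound = 3.0 / np.sqrt(curve.pair_count[finite])
        assert np.all(np.abs(curve.I[finite]) < bound)

    def test_plane_wave_follows_bessel_profile(self):
        """Radially binned I(d) of a planted plane wave is J0(k d): first
        trough at 0.61 wavelengths, first positive peak at 1.117."""
        field = _planted_cosine_field(45.0)
        curve = moran_correlogram(field, bin_width=1.0)
        est = dominant_length_from_correlogram(curve)
        assert est.found
        assert abs(est.dominant_length - 1.117 * 45.0) <= 2.0
        sl = (curve.distance > 15) & (curve.distance < 35)
        trough = curve.distance[sl][np.nanargmin(curve.I[sl])]
        assert abs(trough - 0.61 * 45.0) <= 3.0

    def test_city_spots_peak_at_planted_spacing(self):
        """For compact cluster (spot) patterns the first peak is the spacing."""
        grid = SpatialGrid.square(270.0, 270)
        from citypatterns import FieldSpec, generate

        field = generate(FieldSpec("city_lattice", dict(spacing=45.0)), grid)
        est = dominant_length_from_correlogram(moran_correlogram(field, bin_width=1.0))
        assert est.found and abs(est.dominant_length - 45.0) <= 1.0

    def test_bin_much_narrower_than_grid_spacing_rejected(self):
        grid = SpatialGrid.square(270.0, 90)  # 3 km cells
        from citypatterns import FieldSpec, generate

        field = generate(FieldSpec("city_lattice", dict(spacing=45.0)), grid)
        with pytest.raises(ParameterError, match="spacing"):
            moran_correlogram(field, bin_width=1.0)

    def test_affine_invariance(self):
        field = _planted_cosine_field(45.0, noise_sd=50.0, seed=1)
        c1 = moran_correlogram(field)
        c2 = moran_correlogram(field.with_values(-3.0 * field.values + 7000.0))
        np.testing.assert_allclose(c1.I, c2.I, atol=1e-12)

    def test_zero_variance_rejected(self):
        grid = SpatialGrid.square(100.0, 16)
        with pytest.raises(DegenerateInputError):
            moran_correlogram(ScalarField.constant(grid, 5.0), bin_width=7.0)

    def test_max_distance_beyond_half_extent_rejected(self):
        field = _planted_cosine_field(45.0)
        with pytest.raises(ParameterError):
            moran_correlogram(field, max_distance=120.0)


class TestMoranPoints:
    def test_grid_centre_sampling_matches_field_path(self):
        """Point-set Moran on all grid centres equals the FFT grid path."""
        field = _planted_cosine_field(15.0, extent=48.0, points=12, noise_sd=50.0, seed=2)
        X, Y = field.grid.coords()
        pts = PointSet(np.column_stack([X.ravel(), Y.ravel()]), field.values.ravel())
        c_field = moran_correlogram(field, bin_width=3.0)
        c_pts = moran_correlogram(
            pts, bin_width=3.0, max_distance=24.0, periodic_extent=field.grid.extent
        )
        np.testing.assert_allclose(c_field.I, c_pts.I, atol=1e-10)

    def test_minimum_points(self):
        with pytest.raises(ParameterError):
            PointSet(np.zeros((2, 2)), np.zeros(2))


class TestDominantLength:
    def _curve(self, I):
        d = np.arange(len(I)) + 0.5
        return Correlogram(d, np.asarray(I, dtype=float), np.full(len(I), 100), 1.0)

    def test_single_peak(self):
        I = -0.1 * np.ones(80)
        I[45] = 0.4
        est = dominant_length_from_correlogram(self._curve(I))
        assert est.dominant_length == pytest.approx(45.5, abs=1.0)

    def test_monotone_decay_gives_no_peak(self):
        est = dominant_length_from_correlogram(self._curve(np.linspace(1, 0, 60)))
        assert not est.found and est.dominant_length is None

    def test_first_of_two_peaks_wins_second_listed(self):
        I = np.full(80, -0.05)
        I[43] = 0.30
        I[58] = 0.25
        est = dominant_length_from_correlogram(self._curve(I))
        assert est.dominant_length == pytest.approx(43.5, abs=1.0)
        assert len(est.secondary_lengths) == 1
        assert est.secondary_lengths[0] == pytest.approx(58.5, abs=1.0)

    def test_subthreshold_peak_ignored(self):
        I = np.full(80, 0.0)
        I[40] = 0.01  # below the 0.02 prominence threshold
        est = dominant_length_from_correlogram(self._curve(I))
        assert not est.found


class TestTransect:
    def test_pure_cosine(self):
        x = np.arange(0, 200.0, 1.0)
        spec = transect_power_spectrum(np.cos(2 * np.pi * x / 50.0), spacing=1.0)
        assert spec.dominant_wavelength == pytest.approx(50.0)
        assert spec.prominent

    def test_stronger_mode_wins(self):
        x = np.arange(0, 180.0, 1.0)
        vals = 2.0 * np.cos(2 * np.pi * x / 45.0) + np.cos(2 * np.pi * x / 20.0)
        spec = transect_power_spectrum(vals, spacing=1.0)
        assert spec.dominant_wavelength == pytest.approx(45.0)

    def test_white_noise_not_prominent(self):
        flagged = 0
        for seed in range(100):
            vals = np.random.default_rng(seed).normal(size=128)
            spec = transect_power_spectrum(vals, spacing=1.0)
            flagged += not spec.prominent
        assert flagged >= 90

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            transect_power_spectrum(np.full(64, 3.0), spacing=1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            transect_power_spectrum(np.arange(8.0), spacing=1.0)


class TestPlantedRecovery:
    """Both estimators recover planted scales under 25 % amplitude noise."""

    @pytest.mark.parametrize("wavelength", [20.0, 45.0, 60.0])
    def test_moran_recovery_rate(self, wavelength):
        """Planted wavelength back out of the correlogram peak; under radial
        binning a wave pattern peaks at the J0 maximum 1.117 L, so that
        factor is divided out before comparing. A 0.1 prominence floor is
        used: fully coherent planted waves produce small discrete-lattice
        ripples near the J0 zeros that the default 0.02 threshold (meant
        for weak empirical patterns) would pick up."""
        hits = 0
        n_seeds = 40
        extent = 3 * wavelength
        grid = SpatialGrid.square(extent, int(3 * wavelength))  # 1 km cells
        for seed in range(n_seeds):
            field = _planted_cosine_field(
                wavelength, extent=extent, points=int(extent), noise_sd=200.0,
                seed=seed,
            )
            est = dominant_length_from_correlogram(
                moran_correlogram(field, bin_width=1.0),
                min_distance=wavelength / 2,
                prominence=0.1,
            )
            if est.found and abs(est.dominant_length / 1.117 - wavelength) <= 1.5:
                hits += 1
        assert hits >= 0.95 * n_seeds

    @pytest.mark.parametrize("wavelength", [20.0, 45.0, 60.0])
    def test_transect_recovery_rate(self, wavelength):
        x = np.arange(0, 180.0, 1.0)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            vals = 800.0 * np.cos(2 * np.pi * x / wavelength)
            vals = vals + np.random.default_rng(seed).normal(scale=200.0, size=len(x))
            spec = transect_power_spectrum(vals, spacing=1.0)
            harmonic = round(180.0 / spec.dominant_wavelength)
            if abs(harmonic - round(180.0 / wavelength)) <= 1:
                hits += 1
        assert hits >= 95
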