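"""BEV plane frames, resampling, shifting, posterior classification,
attenuation."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from imucheck.dose_ops import (
    B_AXIS,
    CorrectionConfig,
    apply_attenuation,
    beam_unit_vectors,
    bev_plane_for_beam,
    classify_posterior,
    sample_plane,
    shift_plane,
)
from imucheck.rt_model import DoseGrid

from conftest import make_monaco_beam, make_plane


def _smooth_grid(rng, shape=(20, 22, 24), spacing=(5.0, 5.0, 5.0)):
    vals = gaussian_filter(rng.random(shape), 2.0) + 1.0
    return DoseGrid(
        values=vals,
        origin=-0.5 * (np.asarray(shape)[::-1] - 1) * np.asarray(spacing),
        spacing=np.asarray(spacing, float),
    )


class TestBeamFrame:
    @pytest.mark.parametrize("gantry", [0.0, 37.5, 90.0, 180.0, 250.3, 359.0])
    def test_orthonormal_right_handed_and_b_perpendicular(self, gantry):
        u, v, n = beam_unit_vectors(gantry)
        for a in (u, v, n):
            assert np.linalg.norm(a) == pytest.approx(1.0)
        assert abs(np.dot(u, v)) < 1e-12
        assert np.allclose(np.cross(u, v), n)
        # BEV-Y is always perpendicular to the B-field and the beam axis
        assert abs(np.dot(v, B_AXIS)) < 1e-12
        assert abs(np.dot(v, n)) < 1e-12

    def test_gantry0_geometry(self):
        u, v, n = beam_unit_vectors(0.0)
        assert np.allclose(n, [0, 1, 0])  # anterior source, beam toward posterior
        assert np.allclose(v, [1, 0, 0])  # lateral
        assert np.allclose(u, [0, 0, 1])  # superior-inferior (leaf travel)

    def test_plane_contains_reference_point(self):
        beam = make_monaco_beam(gantry=77.0)
        ref = np.array([3.0, -4.0, 5.0])
        spec = bev_plane_for_beam(beam, ref, 1.0, (11, 11))
        assert np.allclose(spec.points()[5, 5], ref)


class TestSamplePlane:
    def test_constant_field(self, rng):
        grid = _smooth_grid(rng)
        grid.values[:] = 2.0
        beam = make_monaco_beam(gantry=30.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 2.0, (15, 15))
        plane = sample_plane(grid, spec)
        assert np.allclose(plane.values, 2.0)

    def test_linear_ramp_exact(self, rng):
        # trilinear interpolation is exact on a linear field D = z
        grid = _smooth_grid(rng)
        z = grid.origin[2] + np.arange(grid.values.shape[0]) * grid.spacing[2]
        grid.values[:] = z[:, None, None]
        beam = make_monaco_beam(gantry=45.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 1.5, (21, 21))
        plane = sample_plane(grid, spec)
        expected = spec.points()[..., 2]
        assert np.allclose(plane.values, expected, atol=1e-9)

    def test_matches_independent_interpolator(self, rng):
        grid = _smooth_grid(rng)
        beam = make_monaco_beam(gantry=123.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 2.0, (17, 19))
        plane = sample_plane(grid, spec)
        axes = [
            grid.origin[k] + np.arange(grid.values.shape[2 - k]) * grid.spacing[k]
            for k in range(3)
        ]
        oracle = RegularGridInterpolator(
            (axes[2], axes[1], axes[0]), grid.values, method="linear"
        )
        pts = spec.points().reshape(-1, 3)
        expected = oracle(pts[:, ::-1]).reshape(plane.values.shape)
        assert np.allclose(plane.values, expected, atol=1e-6)

    def test_linearity_in_grid_values(self, rng):
        g1, g2 = _smooth_grid(rng), _smooth_grid(rng)
        combo = DoseGrid(values=2.0 * g1.values + 3.0 * g2.values, origin=g1.origin, spacing=g1.spacing)
        beam = make_monaco_beam(gantry=10.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 2.0, (11, 11))
        lhs = sample_plane(combo, spec).values
        rhs = 2.0 * sample_plane(g1, spec).values + 3.0 * sample_plane(g2, spec).values
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_outside_samples_are_nan_not_zero(self, rng):
        grid = _smooth_grid(rng, shape=(8, 8, 8))
        beam = make_monaco_beam(gantry=0.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 10.0, (21, 21))
        plane = sample_plane(grid, spec)
        assert np.isnan(plane.values).any()
        assert np.nanmin(plane.values) > 0  # never silently zero-filled

    def test_wholly_outside_raises(self, rng):
        grid = _smooth_grid(rng, shape=(6, 6, 6))
        beam = make_monaco_beam(gantry=0.0)
        spec = bev_plane_for_beam(beam, np.array([0.0, 500.0, 0.0]), 1.0, (5, 5))
        with pytest.raises(ValueError, match="outside"):
            sample_plane(grid, spec)


class TestShiftPlane:
    def test_zero_shift_identity(self, rng):
        plane = make_plane(rng.random((12, 12)))
        out = shift_plane(plane, 0.0)
        assert np.array_equal(out.values, plane.values)

    def test_integer_lattice_shift_is_a_roll(self, rng):
        vals = rng.random((10, 8))
        plane = make_plane(vals, spacing=2.0)
        out = shift_plane(plane, 2.0)  # one lattice step along +v (rows)
        assert np.allclose(out.values[1:], vals[:-1])
        assert np.isnan(out.values[0]).all()
        assert out.shift_applied_mm == 2.0

    def test_roundtrip_on_smooth_field(self):
        v = np.linspace(0, 1, 40)
        vals = np.sin(2 * np.pi * v)[:, None] * np.ones((1, 30))
        plane = make_plane(vals, spacing=1.0)
        back = shift_plane(shift_plane(plane, 2.0), -2.0)
        interior = np.s_[5:-5, :]
        assert np.allclose(back.values[interior], vals[interior], atol=5e-3)

    def test_oversize_shift_raises(self, rng):
        plane = make_plane(rng.random((10, 10)))
        with pytest.raises(ValueError):
            shift_plane(plane, 11.0)


class TestPosteriorClassification:
    @pytest.mark.parametrize(
        "gantry,expected",
        [(180.0, True), (0.0, False), (100.0, True), (260.0, True), (99.9, False), (260.1, False)],
    )
    def test_default_interval_closed(self, gantry, expected):
        beam = make_monaco_beam(gantry=gantry)
        assert classify_posterior(beam, CorrectionConfig()) is expected

    def test_wraparound_interval(self):
        cfg = CorrectionConfig(posterior_gantry_range=(300.0, 60.0))
        assert classify_posterior(make_monaco_beam(gantry=350.0), cfg)
        assert classify_posterior(make_monaco_beam(gantry=30.0), cfg)
        assert not classify_posterior(make_monaco_beam(gantry=180.0), cfg)


class TestAttenuation:
    def test_posterior_factor_printed_value(self):
        plane = make_plane(np.full((5, 5), 1.0))  # 100 cGy
        out = apply_attenuation(plane, 0.978)
        assert np.allclose(out.values, 0.978)  # 97.8 cGy
        assert out.attenuation_applied == pytest.approx(0.978)

    def test_identity_and_inverse(self, rng):
        plane = make_plane(rng.random((6, 6)))
        assert np.array_equal(apply_attenuation(plane, 1.0).values, plane.values)
        back = apply_attenuation(apply_attenuation(plane, 0.9), 1 / 0.9)
        assert np.allclose(back.values, plane.values, atol=1e-12)

    def test_invalid_factor_raises(self, rng):
        with pytest.raises(ValueError):
            apply_attenuation(make_plane(rng.random((4, 4))), 0.0)

    def test_commutes_with_extraction_and_shift(self, rng):
        grid = _smooth_grid(rng)
        beam = make_monaco_beam(gantry=200.0)
        spec = bev_plane_for_beam(beam, np.zeros(3), 2.0, (15, 15))
        a = shift_plane(apply_attenuation(sample_plane(grid, spec), 0.978), 2.0)
        b = apply_attenuation(shift_plane(sample_plane(apply_attenuation(grid, 0.978), spec), 2.0), 1.0)
        assert np.allclose(a.values, b.values, atol=1e-12, equal_nan=True)
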