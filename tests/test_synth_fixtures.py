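"""Toy dose engine physics and synthetic-case generation."""

import filecmp
from dataclasses import replace

import numpy as np
import pytest

from imucheck.dose_ops import (
    CorrectionConfig,
    bev_plane_for_beam,
    sample_grid_point,
    sample_plane,
    shift_plane,
)
from imucheck.rt_model import PlanRecord, Dialect, read_rtdose, read_rtplan
from imucheck.synth_fixtures import (
    PhantomSpec,
    SlabSpec,
    ToyEngineConfig,
    inject_mismatch,
    make_synthetic_case,
    random_plan,
    toy_dose_engine,
)

from conftest import make_monaco_beam


def _single_beam_plan(beam):
    return PlanRecord(dialect=Dialect.MONACO, beams=[beam], reference_point=np.zeros(3))


@pytest.fixture(scope="module")
def calib_setup():
    """10x10-cm open field, gantry 0, phantom surface at 138.5-cm SSD
    (5 cm above the isocenter)."""
    beam = make_monaco_beam(half_u=5.0, half_v=5.0, mu=100.0)
    phantom = PhantomSpec(size=(240.0, 200.0, 240.0), center=(0.0, 50.0, 0.0))
    return _single_beam_plan(beam), phantom


class TestEnginePhysics:
    def test_calibration_point(self, calib_setup):
        """100 MU deliver 100 cGy at the calibration depth/SSD."""
        plan, phantom = calib_setup
        cfg = ToyEngineConfig(grid_spacing_mm=2.0)
        grid = toy_dose_engine(plan, phantom, cfg)[0]
        d = sample_grid_point(grid, np.zeros(3)) * 100.0  # cGy at isocenter
        assert d == pytest.approx(100.0, rel=0.01)

    def test_mu_linearity(self, calib_setup):
        plan, phantom = calib_setup
        cfg = ToyEngineConfig(grid_spacing_mm=4.0)
        g1 = toy_dose_engine(plan, phantom, cfg)[0]
        plan2 = _single_beam_plan(replace(plan.beams[0], mu=200.0))
        g2 = toy_dose_engine(plan2, phantom, cfg)[0]
        assert np.allclose(g2.values, 2.0 * g1.values, atol=1e-12)

    def test_inverse_square_on_axis(self, calib_setup):
        """With attenuation off, the on-axis falloff is exactly (SAD/w)^2."""
        plan, phantom = calib_setup
        cfg = ToyEngineConfig(grid_spacing_mm=2.0, atten_coeff_per_cm=0.0)
        grid = toy_dose_engine(plan, phantom, cfg)[0]
        d0 = sample_grid_point(grid, np.array([0.0, 0.0, 0.0]))
        d1 = sample_grid_point(grid, np.array([0.0, 100.0, 0.0]))
        w0, w1 = 1435.0, 1535.0
        assert d1 / d0 == pytest.approx((w0 / w1) ** 2, rel=1e-3)

    def test_coil_slab_transmission_ratio(self):
        """Posterior beam through the coil slab vs slab removed: the dose
        ratio equals the configured Beer-Lambert transmission (0.978)."""
        beam = make_monaco_beam(gantry=180.0, half_u=3.0, half_v=2.1)
        plan = _single_beam_plan(beam)
        with_coil = PhantomSpec.default()
        without = replace(with_coil, coil=None)
        cfg = ToyEngineConfig(grid_spacing_mm=4.0)
        g1 = toy_dose_engine(plan, with_coil, cfg)[0]
        g0 = toy_dose_engine(plan, without, cfg)[0]
        sel = g0.values > 0.1 * g0.values.max()
        ratio = g1.values[sel] / g0.values[sel]
        expected = np.exp(-0.05 * 0.445 * 1.0)
        assert np.allclose(ratio, expected, atol=1e-9)
        assert expected == pytest.approx(0.978, abs=5e-4)

    def test_anterior_beam_misses_slabs(self):
        beam = make_monaco_beam(gantry=0.0)
        plan = _single_beam_plan(beam)
        cfg = ToyEngineConfig(grid_spacing_mm=4.0)
        g1 = toy_dose_engine(plan, PhantomSpec.default(), cfg)[0]
        g0 = toy_dose_engine(plan, PhantomSpec.default(with_slabs=False), cfg)[0]
        assert np.allclose(g1.values, g0.values, atol=1e-12)

    @pytest.mark.parametrize("gantry", [0.0, 135.0])
    def test_bfield_shift_self_consistency(self, gantry):
        """Engine shift d undone by shift_plane(-d) within 1 % of local dose."""
        beam = make_monaco_beam(gantry=gantry, half_u=3.0, half_v=2.1)
        plan = _single_beam_plan(beam)
        phantom = PhantomSpec.default(with_slabs=False, size_mm=160.0)
        # attenuation off to isolate the shift mechanism: for gantries where
        # the entry surface is oblique to the beam, depth has a gradient
        # along v and a rigid shift cannot undo the mu * shift residual —
        # the known first-order limit of the lateral-shift approximation
        cfg = ToyEngineConfig(atten_coeff_per_cm=0.0)
        g_shift = toy_dose_engine(plan, phantom, replace(cfg, bfield_shift_mm=2.0))[0]
        g_plain = toy_dose_engine(plan, phantom, cfg)[0]
        spec = bev_plane_for_beam(beam, np.zeros(3), 1.0, (81, 81))
        p_shift = shift_plane(sample_plane(g_shift, spec), -2.0)
        p_plain = sample_plane(g_plain, spec)
        sel = p_plain.valid & p_shift.valid & (p_plain.values > 0.1 * np.nanmax(p_plain.values))
        err = np.abs(p_shift.values[sel] - p_plain.values[sel])
        assert err.max() <= 0.01 * np.nanmax(p_plain.values)

    def test_phantom_behind_source_raises(self):
        beam = make_monaco_beam(gantry=0.0)
        plan = _single_beam_plan(beam)
        huge = PhantomSpec(size=(100.0, 4000.0, 100.0))
        with pytest.raises(ValueError):
            toy_dose_engine(plan, huge, ToyEngineConfig(grid_spacing_mm=10.0))


class TestCaseGeneration:
    def test_same_seed_is_byte_identical(self, tmp_path):
        c1 = make_synthetic_case("det", seed=4, n_beams=2, grid_spacing_mm=4.0)
        c2 = make_synthetic_case("det", seed=4, n_beams=2, grid_spacing_mm=4.0)
        for a, b in zip(c1.reference + c1.evaluated, c2.reference + c2.evaluated):
            assert np.array_equal(a.values, b.values)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        c1.write(p1)
        c2.write(p2)
        for rel in ["det_rtplan.dcm", "reference/beam01.dcm", "evaluated/beam02.dcm", "det_manifest.json"]:
            assert filecmp.cmp(p1 / rel, p2 / rel, shallow=False), rel

    def test_written_case_rereads_cleanly(self, tmp_path):
        case = make_synthetic_case("io", seed=6, n_beams=2, grid_spacing_mm=4.0)
        paths = case.write(tmp_path)
        plan = read_rtplan(paths["plan"])
        from imucheck.rt_model import validate_plan

        assert validate_plan(plan).ok
        grid = read_rtdose(sorted(paths["reference"].glob("*.dcm"))[0])
        quant = case.reference[0].values.max() / (2**32 - 1)
        assert np.allclose(grid.values, case.reference[0].values, atol=quant)


@pytest.fixture(scope="module")
def case():
    return make_synthetic_case("mm", seed=8, n_beams=2, noise_sd_pct=0.0)


class TestMismatchInjection:
    def test_unknown_kind_raises(self, case):
        with pytest.raises(ValueError, match="unknown"):
            inject_mismatch(case, "bogus", 1.0, seed=1)

    def test_zero_magnitude_is_identity(self, case):
        out = inject_mismatch(case, "leaf_shift", 0.0, seed=1)
        for a, b in zip(out.evaluated, case.evaluated):
            assert np.array_equal(a.values, b.values)

    def test_mu_error_scales_evaluated_only(self, case):
        out = inject_mismatch(case, "mu_error", 0.1, seed=1)
        for a, b in zip(out.evaluated, case.evaluated):
            assert np.allclose(a.values, 1.1 * b.values, atol=1e-12)
        for a, b in zip(out.reference, case.reference):
            assert a is b

    def test_manifest_records_perturbation(self, case):
        out = inject_mismatch(case, "leaf_shift", 5.0, seed=2, beam_numbers=[2])
        entries = {e["beam_number"]: e for e in out.manifest["beams"]}
        assert entries[2]["mismatch"]["kind"] == "leaf_shift"
        assert entries[2]["expected_match"] is False
        assert entries[1]["mismatch"] is None and entries[1]["expected_match"] is True

    def test_missing_coil_correction_no_change_on_anterior_beam(self):
        beam = make_monaco_beam(gantry=0.0)
        plan = _single_beam_plan(beam)
        case = make_synthetic_case("ant", seed=9, plan=plan, noise_sd_pct=0.0)
        out = inject_mismatch(case, "missing_coil_correction", 1.0, seed=3)
        assert np.allclose(out.evaluated[0].values, case.evaluated[0].values, atol=1e-12)
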