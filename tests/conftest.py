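import numpy as np
import pytest

from imucheck.dose_ops import DosePlane, PlaneSpec
from imucheck.rt_model import (
    ApertureGeometry,
    BeamRecord,
    ControlPointRecord,
    Dialect,
    PlanRecord,
    Technique,
)


def make_monaco_beam(
    beam_number=1,
    gantry=0.0,
    half_u=3.0,
    half_v=2.1,
    mu=100.0,
    isocenter=(0.0, 0.0, 0.0),
    n_segments=1,
):
    """Rectangular-field monaco beam: leaves at +/- half_u over the pairs
    covering +/- half_v (cm at the 143.5-cm plane)."""
    geometry = ApertureGeometry.unity()
    centers = 0.5 * (geometry.leaf_boundaries[:-1] + geometry.leaf_boundaries[1:])
    inside = np.abs(centers) <= half_v
    cps = []
    for _ in range(n_segments):
        a = np.where(inside, -half_u, 0.0)
        b = np.where(inside, half_u, 0.0)
        cps.append(
            ControlPointRecord(
                mu_weight=1.0 / n_segments,
                leaf_bank_a=a,
                leaf_bank_b=b,
                jaw_x=None,
                jaw_y=(-11.0, 11.0),
            )
        )
    return BeamRecord(
        dialect=Dialect.MONACO,
        beam_number=beam_number,
        name=f"B{beam_number:02d}",
        gantry_angle=gantry,
        collimator_angle=0.0,
        sad=143.5,
        source_distance=143.5,
        technique=Technique.SAD,
        energy_label="7MV-FFF",
        mu=mu,
        control_points=cps,
        isocenter=np.asarray(isocenter, dtype=float),
        geometry=geometry,
    )


def make_monaco_plan(n_beams=2, **kw):
    beams = [make_monaco_beam(beam_number=i + 1, gantry=360.0 * i / n_beams, **kw) for i in range(n_beams)]
    return PlanRecord(dialect=Dialect.MONACO, beams=beams, reference_point=np.zeros(3))


def make_plane(values, spacing=1.0, role="reference"):
    """DosePlane on a gantry-0 frame for standalone gamma tests."""
    values = np.asarray(values, dtype=float)
    nv, nu = values.shape
    spec = PlaneSpec(
        origin=np.zeros(3),
        axis_u=np.array([0.0, 0.0, 1.0]),
        axis_v=np.array([1.0, 0.0, 0.0]),
        normal=np.array([0.0, 1.0, 0.0]),
        spacing=spacing,
        extent=(nu, nv),
    )
    return DosePlane(values=values, spec=spec, role=role)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def matched_case6():
    """Shared 6-beam matched case with the study noise level (1 % of max)."""
    from imucheck.synth_fixtures import make_synthetic_case

    return make_synthetic_case("shared6", seed=11, n_beams=6, noise_sd_pct=1.0)
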