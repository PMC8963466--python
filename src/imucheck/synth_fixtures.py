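"""Synthetic end-to-end cases: toy dose engine, paired grids, mismatches.

The toy engine stands in for the two commercial dose calculators so the
whole second-check chain runs offline.  Per beam it computes

    D(p) = MU * C * (SAD / w)^2 * exp(-mu * depth) * F(t, s)

where w is the source distance along the central axis, depth the water-
equivalent path from the phantom entry, and F the control-point-weighted
aperture fluence at the isocenter plane — rasterized aperture convolved
with a Gaussian penumbra, multiplied by a linear FFF off-axis falloff, and
(on the reference side) rigidly translated along the stacking axis v to
emulate the 1.5-T lateral-shift effect.  Rays crossing the posterior couch
or coil slab are attenuated by Beer-Lambert transmission.  C is fixed by
the 1 cGy/MU calibration at 138.5-cm SSD and 5.0-cm depth.

Both sides of a synthetic case share this engine and differ only in the
B-field shift and the coil slab (the second-calculation side has no
B-field and ignores the coil); a matched case therefore passes gamma near
100 % by construction, and the pipeline's shift and attenuation
corrections are the only discriminators — exactly what the mismatch
sensitivity suite exercises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dose_ops import beam_unit_vectors
from .rt_model import (
    ApertureGeometry,
    BeamRecord,
    ControlPointRecord,
    Dialect,
    DoseGrid,
    PlanRecord,
    Technique,
    write_rtdose,
    write_rtplan,
)

__all__ = [
    "SlabSpec",
    "PhantomSpec",
    "ToyEngineConfig",
    "SyntheticCase",
    "toy_dose_engine",
    "make_synthetic_case",
    "inject_mismatch",
    "make_sensitivity_suite",
    "random_beam",
    "random_plan",
    "MISMATCH_KINDS",
]

MISMATCH_KINDS = ("mu_error", "leaf_shift", "wrong_shift_sign", "missing_coil_correction")


def make_sensitivity_suite(
    seed: int,
    n_beams: int = 94,
    n_mismatch: int = 18,
    noise_sd_pct: float = 1.0,
    mu_error_range: tuple[float, float] = (0.06, 0.10),
    leaf_shift_range_mm: tuple[float, float] = (5.0, 6.0),
) -> tuple[list["SyntheticCase"], list[bool]]:
    """Scaled replica of a commissioning sensitivity design: ``n_beams``
    synthetic beams across several plans, ``n_mismatch`` of them perturbed
    (half MU errors, half whole-bank leaf shifts), magnitudes recorded in
    each manifest.

    Returns the cases and the per-beam ground truth (True = expected to
    match), ordered as the beams appear across cases.
    """
    rng = np.random.default_rng(seed)
    sizes = []
    remaining = n_beams
    while remaining > 0:
        take = min(15, remaining)
        sizes.append(take)
        remaining -= take
    flat_index = rng.choice(n_beams, size=n_mismatch, replace=False)
    mismatched = set(int(i) for i in flat_index)

    cases, truth = [], []
    offset = 0
    for ci, size in enumerate(sizes):
        case = make_synthetic_case(
            f"sens{ci:02d}", seed=seed + 101 + ci, n_beams=size, noise_sd_pct=noise_sd_pct
        )
        local = [i - offset for i in mismatched if offset <= i < offset + size]
        for j, li in enumerate(sorted(local)):
            beam_no = case.plan.beams[li].beam_number
            if (offset + li) % 2 == 0:
                kind = "mu_error"
                mag = float(rng.uniform(*mu_error_range))
            else:
                kind = "leaf_shift"
                mag = float(rng.uniform(*leaf_shift_range_mm))
            case = inject_mismatch(
                case, kind, mag, seed=seed + 500 + offset + li, beam_numbers=[beam_no]
            )
        cases.append(case)
        truth.extend((offset + k) not in mismatched for k in range(size))
        offset += size
    return cases, truth


@dataclass(frozen=True)
class SlabSpec:
    """Horizontal attenuating slab (couch or RF coil), infinite in x and z.

    ``y_top`` is the anterior face (mm, patient frame, +y posterior);
    density is relative to water and feeds the engine's attenuation
    coefficient.
    """

    y_top: float
    thickness: float  # mm
    density: float

    def __post_init__(self):
        if self.thickness <= 0 or self.density <= 0:
            raise ValueError("slab thickness and density must be positive")

    @property
    def y_bottom(self) -> float:
        return self.y_top + self.thickness


@dataclass(frozen=True)
class PhantomSpec:
    """Uniform box phantom with optional posterior couch and coil slabs."""

    size: tuple[float, float, float] = (300.0, 300.0, 300.0)  # mm (x, y, z)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    density: float = 1.0
    couch: SlabSpec | None = None
    coil: SlabSpec | None = None

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("phantom dimensions must be positive")
        if self.density <= 0:
            raise ValueError("phantom density must be positive")

    @classmethod
    def default(cls, with_slabs: bool = True, size_mm: float = 200.0) -> "PhantomSpec":
        # coil transmission exp(-0.05 * 0.445 * 1 cm) ~= 0.978 (the posterior
        # RF coil), couch exp(-0.05 * 0.305 * 2 cm) ~= 0.970; slabs sit just
        # posterior of the phantom
        y_hi = size_mm / 2.0
        coil = SlabSpec(y_top=y_hi + 10.0, thickness=10.0, density=0.445) if with_slabs else None
        couch = SlabSpec(y_top=y_hi + 25.0, thickness=20.0, density=0.305) if with_slabs else None
        return cls(size=(size_mm, size_mm, size_mm), center=(0.0, 0.0, 0.0), couch=couch, coil=coil)

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.size) / 2.0

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.size) / 2.0


@dataclass(frozen=True)
class ToyEngineConfig:
    """Fixture conventions of the toy engine (not clinical beam data).

    ``mu_calibration`` cGy/MU at 138.5-cm SSD and 5.0-cm depth matches the
    machine calibration; the rest are deliberately simple water-like
    values.
    """

    mu_calibration: float = 1.0  # cGy/MU at calib_depth / calib_ssd
    calib_depth_cm: float = 5.0
    calib_ssd_cm: float = 138.5
    atten_coeff_per_cm: float = 0.05
    penumbra_sigma_mm: float = 3.0
    fff_slope_per_cm: float = 0.015
    bfield_shift_mm: float = 0.0  # lateral profile shift along +v
    noise_sd_pct: float = 0.0  # Gaussian noise, percent of beam max dose
    seed: int = 0
    grid_spacing_mm: float = 2.0
    fluence_cell_cm: float = 0.1

    def __post_init__(self):
        if self.mu_calibration <= 0:
            raise ValueError("mu_calibration must be positive")
        if self.penumbra_sigma_mm < 0 or self.noise_sd_pct < 0:
            raise ValueError("sigma and noise must be >= 0")


def _fluence_map(beam: BeamRecord, cfg: ToyEngineConfig):
    """CP-weighted aperture fluence on a (v, u) lattice at the definition
    plane, penumbra-smoothed and FFF-weighted.  Returns (F, u0_cm, v0_cm)."""
    cell = cfg.fluence_cell_cm
    half = beam.geometry.max_half_field + max(beam.geometry.span / 2.0, 1.0) + 3.0
    n = int(np.ceil(2 * half / cell)) + 1
    u_ax = (np.arange(n) - (n - 1) / 2.0) * cell
    v_ax = u_ax.copy()
    F = np.zeros((n, n))
    from .aperture_ciao import aperture_rectangles

    for cp in beam.control_points:
        seg = np.zeros((n, n))
        for (u0, u1, v0, v1) in aperture_rectangles(cp, beam.geometry):
            su = (u_ax >= u0) & (u_ax <= u1)
            sv = (v_ax >= v0) & (v_ax <= v1)
            seg[np.ix_(sv, su)] = 1.0
        F += cp.mu_weight * seg
    sigma_cells = cfg.penumbra_sigma_mm / 10.0 / cell
    if sigma_cells > 0:
        F = ndimage.gaussian_filter(F, sigma_cells, mode="constant")
    uu, vv = np.meshgrid(u_ax, v_ax)
    r = np.sqrt(uu**2 + vv**2)
    F *= np.maximum(0.0, 1.0 - cfg.fff_slope_per_cm * r)
    return F, u_ax[0], v_ax[0]


def _ray_box_entry(S: np.ndarray, P: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Distance (mm) from the source S to the box entry along each ray S->P.

    Vectorized slab method; rays missing the box return NaN.
    """
    d = P - S[None, :]
    length = np.linalg.norm(d, axis=1)
    dn = d / length[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - S[None, :]) / dn
        t2 = (hi[None, :] - S[None, :]) / dn
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    entry = np.where((tmax >= tmin) & (tmax > 0), np.maximum(tmin, 0.0), np.nan)
    return entry, length, dn


def _slab_transmission(
    S: np.ndarray, P: np.ndarray, dn: np.ndarray, slab: SlabSpec, mu_per_cm: float
) -> np.ndarray:
    """Beer-Lambert transmission for rays whose segment S->P crosses the slab.

    The path length is the slab thickness at normal incidence: the slab
    emulates a thin attenuator with a single flat transmission (the same
    idealization the flat posterior-coil correction makes), so the
    pipeline's scalar correction can cancel it exactly.
    """
    sy, py = S[1], P[:, 1]
    spans = ((sy <= slab.y_top) & (py >= slab.y_bottom)) | (
        (sy >= slab.y_bottom) & (py <= slab.y_top)
    )
    path_cm = slab.thickness / 10.0
    return np.where(spans, np.exp(-mu_per_cm * slab.density * path_cm), 1.0)


def toy_dose_engine(
    plan: PlanRecord,
    phantom: PhantomSpec,
    cfg: ToyEngineConfig,
) -> list[DoseGrid]:
    """Per-beam 3D dose grids (Gy) over the phantom box."""
    lo, hi = phantom.lo, phantom.hi
    spacing = cfg.grid_spacing_mm
    axes = [np.arange(lo[k] + spacing / 2.0, hi[k], spacing) for k in range(3)]
    nx, ny, nz = (len(a) for a in axes)
    X, Y, Z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    P = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    rng = np.random.default_rng(cfg.seed)
    tag = f"toy(shift={cfg.bfield_shift_mm:g}mm)"
    grids = []
    for beam in plan.beams:
        u, v, normal = beam_unit_vectors(beam.gantry_angle)
        S = beam.isocenter - normal * beam.source_distance * 10.0
        rel = P - S[None, :]
        w = rel @ normal  # mm along the central axis
        if np.any(w <= 0):
            raise ValueError(f"beam {beam.name}: phantom extends behind the source")

        # BEV coordinates at the definition plane (cm)
        d_def_mm = beam.sad * 10.0
        t_cm = (rel @ u) / w * d_def_mm / 10.0
        s_cm = (rel @ v) / w * d_def_mm / 10.0

        F, u0, v0 = _fluence_map(beam, cfg)
        cell = cfg.fluence_cell_cm
        shift_cm = cfg.bfield_shift_mm / 10.0
        # profile translated +shift along v: sample the unshifted map at v - shift
        iv = (s_cm - shift_cm - v0) / cell
        iu = (t_cm - u0) / cell
        flu = ndimage.map_coordinates(
            F, np.stack([iv, iu]), order=1, mode="constant", cval=0.0
        )

        entry, length, dn = _ray_box_entry(S, P, lo, hi)
        if np.all(np.isnan(entry)):
            raise ValueError(f"beam {beam.name}: phantom does not cover the field")
        depth_cm = np.clip(length - np.nan_to_num(entry, nan=np.inf), 0.0, None) / 10.0
        depth_cm = np.where(np.isfinite(entry), depth_cm, 0.0) * phantom.density

        mu = cfg.atten_coeff_per_cm
        calib = cfg.mu_calibration * np.exp(mu * cfg.calib_depth_cm * phantom.density)
        invsq = (beam.source_distance * 10.0 / w) ** 2
        dose_cgy = beam.mu * calib * invsq * np.exp(-mu * depth_cm) * flu
        dose_cgy = np.where(np.isfinite(entry), dose_cgy, 0.0)

        for slab in (phantom.couch, phantom.coil):
            if slab is not None:
                dose_cgy *= _slab_transmission(S, P, dn, slab, mu)

        if cfg.noise_sd_pct > 0:
            sd = cfg.noise_sd_pct / 100.0 * dose_cgy.max()
            dose_cgy = np.clip(dose_cgy + rng.normal(0.0, sd, dose_cgy.shape), 0.0, None)

        vals = (dose_cgy / 100.0).reshape(nx, ny, nz).transpose(2, 1, 0)  # (z, y, x)
        origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
        grids.append(
            DoseGrid(
                values=vals,
                origin=origin,
                spacing=np.array([spacing, spacing, spacing]),
                summation="beam",
                source_engine=tag,
                beam_number=beam.beam_number,
            )
        )
    return grids


# ---------------------------------------------------------------------------
# synthetic plans and cases
# ---------------------------------------------------------------------------


def random_beam(
    beam_number: int,
    rng: np.random.Generator,
    gantry: float | None = None,
    n_segments: int | None = None,
    field_half_cm: tuple[float, float] = (1.5, 3.0),
    mu: float | None = None,
) -> BeamRecord:
    """Random monaco-dialect beam with a staircase multi-segment aperture."""
    geometry = ApertureGeometry.unity()
    gantry = float(rng.uniform(0, 360)) if gantry is None else gantry
    n_segments = int(rng.integers(1, 4)) if n_segments is None else n_segments
    mu = float(rng.uniform(80, 200)) if mu is None else mu
    n = geometry.n_leaf_pairs
    centers = 0.5 * (geometry.leaf_boundaries[:-1] + geometry.leaf_boundaries[1:])
    weights = rng.dirichlet(np.ones(n_segments) * 4.0)
    cps = []
    for k in range(n_segments):
        half_u = rng.uniform(*field_half_cm)
        half_v = rng.uniform(*field_half_cm)
        cu = rng.uniform(-1.0, 1.0)
        cv = rng.uniform(-1.0, 1.0)
        bank_a = np.full(n, -0.0)
        bank_b = np.full(n, 0.0)
        inside = np.abs(centers - cv) <= half_v
        # gentle per-leaf staircase
        ragged = rng.uniform(-0.3, 0.3, size=n)
        bank_a[inside] = cu - half_u + ragged[inside]
        bank_b[inside] = cu + half_u - ragged[inside]
        park = centers[~inside] * 0.0
        bank_a[~inside] = park
        bank_b[~inside] = park
        cps.append(
            ControlPointRecord(
                mu_weight=float(weights[k]),
                leaf_bank_a=np.clip(bank_a, -11.0, 11.0),
                leaf_bank_b=np.clip(bank_b, -11.0, 11.0),
                jaw_x=None,
                jaw_y=(-11.0, 11.0),
            )
        )
    # normalize exactly
    total = sum(cp.mu_weight for cp in cps)
    for cp in cps:
        cp.mu_weight /= total
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
        isocenter=np.zeros(3),
        geometry=geometry,
    )


def random_plan(n_beams: int, seed: int, label: str = "synthetic") -> PlanRecord:
    """Monaco-dialect plan of ``n_beams`` random beams, gantry angles spread
    over the full circle."""
    rng = np.random.default_rng(seed)
    gantries = (np.linspace(0, 360, n_beams, endpoint=False) + rng.uniform(0, 360 / max(n_beams, 1))) % 360
    beams = [random_beam(i + 1, rng, gantry=float(gantries[i])) for i in range(n_beams)]
    return PlanRecord(
        dialect=Dialect.MONACO,
        beams=beams,
        reference_point=np.zeros(3),
        fraction_label=label,
    )


@dataclass
class SyntheticCase:
    """A plan plus paired reference/evaluated per-beam dose grids."""

    name: str
    plan: PlanRecord
    reference: list[DoseGrid]
    evaluated: list[DoseGrid]
    manifest: dict

    def write(self, out_dir) -> dict[str, Path]:
        """Write plan, dose files and manifest; deterministic per seed."""
        out = Path(out_dir)
        (out / "reference").mkdir(parents=True, exist_ok=True)
        (out / "evaluated").mkdir(parents=True, exist_ok=True)
        plan_path = out / f"{self.name}_rtplan.dcm"
        write_rtplan(self.plan, plan_path)
        for grid in self.reference:
            write_rtdose(grid, out / "reference" / f"beam{grid.beam_number:02d}.dcm")
        for grid in self.evaluated:
            write_rtdose(grid, out / "evaluated" / f"beam{grid.beam_number:02d}.dcm")
        manifest_path = out / f"{self.name}_manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return {
            "plan": plan_path,
            "reference": out / "reference",
            "evaluated": out / "evaluated",
            "manifest": manifest_path,
        }


def make_synthetic_case(
    name: str,
    seed: int,
    n_beams: int = 15,
    phantom: PhantomSpec | None = None,
    bfield_shift_mm: float = 2.0,
    noise_sd_pct: float = 1.0,
    grid_spacing_mm: float = 2.0,
    plan: PlanRecord | None = None,
    out_dir=None,
) -> SyntheticCase:
    """Matched case: reference grids from the engine with the B-field shift
    and coil slab on, evaluated grids with shift off and the coil ignored
    (the second calculation does not see the coil).  Deterministic per
    seed."""
    phantom = phantom or PhantomSpec.default()
    plan = plan if plan is not None else random_plan(n_beams, seed, label=name)
    ss = np.random.SeedSequence(seed)
    ref_seed, eval_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    ref_cfg = ToyEngineConfig(
        bfield_shift_mm=bfield_shift_mm,
        noise_sd_pct=noise_sd_pct,
        seed=ref_seed,
        grid_spacing_mm=grid_spacing_mm,
    )
    eval_phantom = replace(phantom, coil=None)
    eval_cfg = replace(ref_cfg, bfield_shift_mm=0.0, seed=eval_seed)
    case = SyntheticCase(
        name=name,
        plan=plan,
        reference=toy_dose_engine(plan, phantom, ref_cfg),
        evaluated=toy_dose_engine(plan, eval_phantom, eval_cfg),
        manifest={
            "name": name,
            "seed": seed,
            "bfield_shift_mm": bfield_shift_mm,
            "noise_sd_pct": noise_sd_pct,
            "grid_spacing_mm": grid_spacing_mm,
            "beams": [
                {
                    "beam_number": b.beam_number,
                    "gantry_angle": round(b.gantry_angle, 3),
                    "mu": round(b.mu, 3),
                    "mismatch": None,
                    "expected_match": True,
                }
                for b in plan.beams
            ],
        },
    )
    if out_dir is not None:
        case.write(out_dir)
    return case


def inject_mismatch(
    case: SyntheticCase,
    kind: str,
    magnitude: float,
    seed: int,
    beam_numbers: list[int] | None = None,
) -> SyntheticCase:
    """Perturb the evaluated side of selected beams; the manifest records
    kind and magnitude.

    * ``mu_error`` — evaluated dose scaled by (1 + magnitude), magnitude a
      fraction (0.05 = 5 % MU error);
    * ``leaf_shift`` — both leaf banks of the evaluated-side plan shifted
      by ``magnitude`` mm along the travel axis, dose recomputed;
    * ``wrong_shift_sign`` — evaluated dose computed as if the B-field
      shift (magnitude mm) had wrongly been applied on that side too;
    * ``missing_coil_correction`` — evaluated dose computed with the coil
      slab present (as if its attenuation were already included), so the
      pipeline's posterior correction double-counts; no effect on anterior
      beams.
    """
    if kind not in MISMATCH_KINDS:
        raise ValueError(f"unknown mismatch kind {kind!r}")
    if magnitude < 0:
        raise ValueError("mismatch magnitude must be >= 0")
    if magnitude == 0 and kind in ("mu_error", "leaf_shift"):
        return replace(case, name=case.name + f"_{kind}0")  # explicit no-op
    targets = set(beam_numbers or [b.beam_number for b in case.plan.beams])
    base_cfg = ToyEngineConfig(
        bfield_shift_mm=0.0,
        noise_sd_pct=case.manifest["noise_sd_pct"],
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31),
        grid_spacing_mm=case.manifest["grid_spacing_mm"],
    )
    phantom = PhantomSpec.default()
    eval_phantom = replace(phantom, coil=None)

    new_eval = []
    for beam, grid in zip(case.plan.beams, case.evaluated):
        if beam.beam_number not in targets:
            new_eval.append(grid)
            continue
        sub_plan = PlanRecord(
            dialect=case.plan.dialect,
            beams=[beam],
            reference_point=case.plan.reference_point,
            fraction_label=case.plan.fraction_label,
        )
        if kind == "mu_error":
            g = replace(grid, values=grid.values * (1.0 + magnitude))
            new_eval.append(g)
        elif kind == "leaf_shift":
            d_cm = magnitude / 10.0
            pert = replace(
                beam,
                control_points=[
                    replace(
                        cp,
                        leaf_bank_a=cp.leaf_bank_a + d_cm,
                        leaf_bank_b=cp.leaf_bank_b + d_cm,
                    )
                    for cp in beam.control_points
                ],
            )
            sub_plan.beams = [pert]
            new_eval.append(toy_dose_engine(sub_plan, eval_phantom, base_cfg)[0])
        elif kind == "wrong_shift_sign":
            cfg = replace(base_cfg, bfield_shift_mm=-magnitude)
            new_eval.append(toy_dose_engine(sub_plan, eval_phantom, cfg)[0])
        else:  # missing_coil_correction
            new_eval.append(toy_dose_engine(sub_plan, phantom, base_cfg)[0])

    manifest = json.loads(json.dumps(case.manifest))
    for entry in manifest["beams"]:
        if entry["beam_number"] in targets:
            entry["mismatch"] = {"kind": kind, "magnitude": magnitude, "seed": seed}
            entry["expected_match"] = False
    return SyntheticCase(
        name=case.name + f"_{kind}",
        plan=case.plan,
        reference=case.reference,
        evaluated=new_eval,
        manifest=manifest,
    )
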