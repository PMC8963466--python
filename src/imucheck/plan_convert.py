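"""Monaco -> Eclipse RT Plan transformation.

Three rules make a Unity (SAD 143.5 cm) plan ingestible by a conventional
100-cm-SAD system while leaving the projected aperture in the original
beam's-eye-view plane untouched:

1. rescale every collimating position to the 100-cm plane (factor
   100/143.5, i.e. dividing by 1.435) and switch the beam to the
   extended-SSD technique so the physical source distance is retained;
2. relabel the nominal energy 7MV-FFF -> 6MV-FFF;
3. interchange the in-plane axes: MLCY -> MLCX, collimator 0 -> 90 degrees,
   and synthesize X jaws from the leaf-position envelope (min/max open leaf
   position plus a 5-mm margin, clipped to the physical +/- 7.67-cm
   projection of the +/- 11-cm overtravel) or as the fixed +/- 7.67 cm.

Monitor units are never touched: the second calculation runs with fixed MU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .rt_model import (
    LEAF_CLOSURE_TOL_CM,
    BeamRecord,
    ControlPointRecord,
    Dialect,
    PlanRecord,
    Technique,
    validate_plan,
)

__all__ = [
    "ConversionConfig",
    "ConversionError",
    "rescale_positions",
    "swap_axes",
    "derive_x_jaws",
    "to_extended_ssd",
    "convert_plan",
    "MONACO_SAD_CM",
    "ECLIPSE_SAD_CM",
]

MONACO_SAD_CM = 143.5
ECLIPSE_SAD_CM = 100.0


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionConfig:
    """Parameters of the dialect transformation.

    ``jaw_margin`` and ``fixed_jaw_half`` are cm at the target (100-cm)
    plane; 0.5 cm and 7.67 cm reproduce the clinical defaults.
    """

    target_sad: float = ECLIPSE_SAD_CM
    jaw_margin: float = 0.5
    jaw_mode: str = "from_leaves"  # or "fixed"
    fixed_jaw_half: float = 7.67
    energy_relabel: dict = field(default_factory=lambda: {"7MV-FFF": "6MV-FFF"})

    def __post_init__(self):
        if self.target_sad <= 0:
            raise ValueError("target_sad must be positive")
        if self.jaw_margin < 0:
            raise ValueError("jaw_margin must be >= 0")
        if self.fixed_jaw_half <= 0:
            raise ValueError("fixed_jaw_half must be positive")
        if self.jaw_mode not in ("from_leaves", "fixed"):
            raise ValueError(f"unknown jaw_mode {self.jaw_mode!r}")


def rescale_positions(positions, sad_from: float, sad_to: float):
    """Similar-triangle rescaling of collimating positions between SAD planes.

    Multiplies by ``sad_to / sad_from`` so the projected aperture in the
    original BEV plane is unchanged (143.5 -> 100 cm divides by 1.435).
    """
    if sad_from <= 0 or sad_to <= 0:
        raise ConversionError("SAD values must be positive")
    return np.asarray(positions, dtype=float) * (sad_to / sad_from)


def swap_axes(beam: BeamRecord) -> BeamRecord:
    """Interchange the in-plane axes of a monaco-dialect beam.

    The MLC sequence is relabeled MLCY -> MLCX and the collimator angle set
    to 90 degrees; because the collimator rotation exactly compensates the
    axis interchange, the projected aperture in the patient frame is
    identical before and after (a pure relabeling).
    """
    if beam.dialect != Dialect.MONACO:
        raise ConversionError("swap_axes expects a monaco-dialect beam (already swapped?)")
    if abs(beam.collimator_angle) > 1e-9:
        raise ConversionError(
            f"unsupported input collimator angle {beam.collimator_angle} (must be 0)"
        )
    meta = dict(beam.meta)
    meta["vendor_axis_labels"] = {"monaco": "LW-RW/UL-LL", "eclipse": "X1-X2/Y1-Y2"}
    return replace(beam, dialect=Dialect.ECLIPSE, collimator_angle=90.0, meta=meta)


def derive_x_jaws(
    cp: ControlPointRecord, cfg: ConversionConfig
) -> tuple[float, float]:
    """X-jaw pair (cm at the target plane) for one control point.

    ``from_leaves`` mode: envelope of *open* leaf pairs (gap above the
    0.05-cm closure tolerance, evaluated at the 100-cm plane) plus the
    margin, clipped to +/- ``fixed_jaw_half``.  ``fixed`` mode: the full
    +/- 7.67 cm.  A fully closed segment degenerates to the parked position
    +/- margin, with a warning.
    """
    if cfg.jaw_mode == "fixed":
        return (-cfg.fixed_jaw_half, cfg.fixed_jaw_half)
    tol = LEAF_CLOSURE_TOL_CM * (cfg.target_sad / MONACO_SAD_CM)
    open_mask = cp.open_pairs(tol)
    if not np.any(open_mask):
        warnings.warn("fully closed control point: jaws collapse to parked position")
        center = float(np.median(cp.leaf_bank_a))
        lo, hi = center - cfg.jaw_margin, center + cfg.jaw_margin
    else:
        lo = float(cp.leaf_bank_a[open_mask].min()) - cfg.jaw_margin
        hi = float(cp.leaf_bank_b[open_mask].max()) + cfg.jaw_margin
    lo = max(lo, -cfg.fixed_jaw_half)
    hi = min(hi, cfg.fixed_jaw_half)
    return (lo, hi)


def to_extended_ssd(beam: BeamRecord) -> BeamRecord:
    """Switch a 143.5-cm SAD beam to the extended-SSD technique.

    The nominal SAD becomes 100 cm while ``source_distance`` keeps the
    physical 143.5 cm, so the source position in the patient frame is
    unchanged.  ``to_sad_technique`` is the exact inverse.
    """
    if beam.technique == Technique.EXTENDED_SSD:
        raise ConversionError("beam already uses the extended-SSD technique")
    if abs(beam.sad - MONACO_SAD_CM) > 1e-6:
        raise ConversionError(f"expected SAD {MONACO_SAD_CM} cm, got {beam.sad}")
    return replace(
        beam,
        technique=Technique.EXTENDED_SSD,
        sad=ECLIPSE_SAD_CM,
        source_distance=beam.source_distance,
    )


def to_sad_technique(beam: BeamRecord) -> BeamRecord:
    """Inverse of :func:`to_extended_ssd`."""
    if beam.technique == Technique.SAD:
        raise ConversionError("beam already uses the SAD technique")
    return replace(beam, technique=Technique.SAD, sad=beam.source_distance)


def _convert_beam(beam: BeamRecord, cfg: ConversionConfig) -> BeamRecord:
    factor = cfg.target_sad / beam.sad
    geometry = beam.geometry.scaled(factor)
    new_cps = []
    for cp in beam.control_points:
        scaled = ControlPointRecord(
            mu_weight=cp.mu_weight,
            leaf_bank_a=rescale_positions(cp.leaf_bank_a, beam.sad, cfg.target_sad),
            leaf_bank_b=rescale_positions(cp.leaf_bank_b, beam.sad, cfg.target_sad),
            jaw_x=None,
            jaw_y=cp.jaw_y,
            )
        new_cps.append(scaled)

    energy = cfg.energy_relabel.get(beam.energy_label, beam.energy_label)
    out = replace(beam, control_points=new_cps, geometry=geometry, energy_label=energy)
    out = swap_axes(out)

    # Static jaws per beam: envelope of the per-control-point jaw rule.
    jaw_pairs = [derive_x_jaws(cp, cfg) for cp in new_cps]
    jaw_x = (min(p[0] for p in jaw_pairs), max(p[1] for p in jaw_pairs))
    # The fixed 22-cm superior-inferior extent maps to the Eclipse Y jaws,
    # scaled to the target plane.
    half_span = geometry.span / 2.0
    jaw_y = (-half_span, half_span)
    out.control_points = [
        replace(cp, jaw_x=jaw_x, jaw_y=jaw_y) for cp in out.control_points
    ]
    return to_extended_ssd(out)


def convert_plan(plan: PlanRecord, cfg: ConversionConfig | None = None) -> PlanRecord:
    """Full Monaco -> Eclipse conversion of a validated plan.

    Per beam: rescale positions -> relabel energy -> interchange axes ->
    derive X jaws -> extended-SSD technique.  MU are unchanged.  Converting
    an eclipse-dialect plan raises (no double scaling possible).
    """
    cfg = cfg or ConversionConfig()
    if plan.dialect != Dialect.MONACO:
        raise ConversionError("convert_plan expects a monaco-dialect plan")
    rep = validate_plan(plan)
    if not rep.ok:
        raise ConversionError("input plan invalid: " + "; ".join(rep.issues))
    beams = []
    for bi, beam in enumerate(plan.beams):
        try:
            beams.append(_convert_beam(beam, cfg))
        except Exception as exc:  # abort with beam index per contract
            raise ConversionError(f"beam[{bi}] ({beam.name}): {exc}") from exc
    out = PlanRecord(
        dialect=Dialect.ECLIPSE,
        beams=beams,
        reference_point=plan.reference_point.copy(),
        machine_label=plan.machine_label,
        fraction_label=plan.fraction_label,
    )
    rep = validate_plan(out)
    if not rep.ok:
        raise ConversionError("converted plan invalid: " + "; ".join(rep.issues))
    return out
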