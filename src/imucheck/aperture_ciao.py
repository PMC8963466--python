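"""Complete-irradiated-area-outline (CIAO) masks on the analysis plane.

The CIAO of a beam is the union over all control points of the open MLC
aperture intersected with the jaw window — every point the beam ever
exposes.  It defines the region of interest for the gamma pass rate.
Apertures live at the dialect's isocenter-projection plane in the (u, v)
beam frame (u = leaf travel, v = leaf stacking); projecting to the analysis
plane scales linear dimensions by source-to-plane distance over
source-to-isocenter distance.

Rasterization uses pixel-center containment with ties (a center exactly on
an edge) counted inside; because the apertures are unions of axis-aligned
rectangles this is implemented exactly with interval tests, and shapely
polygons are exposed for area oracles and arbitrary exclusion contours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .rt_model import (
    LEAF_CLOSURE_TOL_CM,
    ApertureGeometry,
    BeamRecord,
    ControlPointRecord,
)
from .dose_ops import PlaneSpec

__all__ = [
    "CiaoMask",
    "aperture_polygon",
    "aperture_rectangles",
    "ciao_mask",
    "subtract_roi",
    "load_contour",
    "projection_factor",
]


def load_contour(path) -> np.ndarray:
    """Read a planar exclusion contour: a JSON list of [u, v] vertices in
    plane coordinates (mm)."""
    import json
    from pathlib import Path

    verts = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    if verts.size and (verts.ndim != 2 or verts.shape[1] != 2):
        raise ValueError(f"{path}: expected a list of [u, v] vertex pairs")
    return verts.reshape(-1, 2)


@dataclass
class CiaoMask:
    """Binary ROI aligned to a DosePlane lattice (``mask[iv, iu]``)."""

    mask: np.ndarray
    source: str
    exclusions_applied: list[str]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def aperture_rectangles(
    cp: ControlPointRecord,
    geometry: ApertureGeometry,
    tol: float | None = None,
) -> list[tuple[float, float, float, float]]:
    """Open-pair rectangles ``(u_lo, u_hi, v_lo, v_hi)`` in cm, jaw-clipped.

    Closed pairs (gap <= tol) contribute nothing; the default closure
    tolerance is 0.05 cm at the 143.5-cm plane, rescaled to the geometry's
    own definition plane so that "open" is a projection-invariant notion.
    ``u`` is the leaf-travel axis, ``v`` the stacking axis.
    """
    if tol is None:
        tol = LEAF_CLOSURE_TOL_CM * (geometry.max_half_field / 11.0)
    u_lo_jaw, u_hi_jaw = cp.travel_window()
    stack = cp.stack_window()
    rects = []
    open_mask = cp.open_pairs(tol)
    for k in np.nonzero(open_mask)[0]:
        u0 = max(float(cp.leaf_bank_a[k]), u_lo_jaw)
        u1 = min(float(cp.leaf_bank_b[k]), u_hi_jaw)
        v0 = float(geometry.leaf_boundaries[k])
        v1 = float(geometry.leaf_boundaries[k + 1])
        if stack is not None:
            v0, v1 = max(v0, stack[0]), min(v1, stack[1])
        if u1 > u0 and v1 > v0:
            rects.append((u0, u1, v0, v1))
    return rects


def aperture_polygon(
    cp: ControlPointRecord,
    geometry: ApertureGeometry,
    tol: float | None = None,
) -> Polygon:
    """Rectilinear aperture polygon (cm, (u, v) frame) of one control point.

    Union over open leaf pairs of ``[bank_a, bank_b] x [leaf boundaries]``
    intersected with the jaw window; empty polygon if all pairs are closed.
    """
    rects = aperture_rectangles(cp, geometry, tol)
    if not rects:
        return Polygon()
    return unary_union([box(u0, v0, u1, v1) for (u0, u1, v0, v1) in rects])


def projection_factor(beam: BeamRecord, spec: PlaneSpec) -> float:
    """Divergence scaling from the aperture definition plane to the
    analysis plane: source-to-plane distance / definition-plane distance."""
    _, _, normal = _beam_frame(beam)
    # distance from source to the analysis plane along the beam axis
    d_plane_mm = beam.source_distance * 10.0 + float(
        np.dot(spec.origin - beam.isocenter, normal)
    )
    # positions are defined `sad` cm from the source (the dialect's
    # isocenter-projection plane)
    d_def_mm = beam.sad * 10.0
    return d_plane_mm / d_def_mm


def _beam_frame(beam: BeamRecord):
    from .dose_ops import beam_unit_vectors

    return beam_unit_vectors(beam.gantry_angle)


def ciao_mask(
    beam: BeamRecord,
    spec: PlaneSpec,
    geometry: ApertureGeometry | None = None,
    dose_threshold: float | None = None,
    dose_plane=None,
) -> CiaoMask:
    """Rasterized union of all control-point apertures on the plane lattice.

    The aperture (cm at the definition plane) is projected to the analysis
    plane by the divergence factor and tested against pixel centers.  An
    optional dose threshold (fraction of the plane maximum, default off)
    can further restrict the ROI.  An empty union raises: there is no ROI
    to analyze.
    """
    geometry = geometry or beam.geometry
    factor = projection_factor(beam, spec)
    u_mm, v_mm = spec.coords()
    nu, nv = spec.extent
    mask = np.zeros((nv, nu), dtype=bool)
    eps = 1e-9  # mm; absorbs ulp-level rescaling noise at exact-tie pixels
    for cp in beam.control_points:
        for (u0, u1, v0, v1) in aperture_rectangles(cp, geometry):
            # cm at definition plane -> mm on the analysis plane
            su = (u_mm >= u0 * 10.0 * factor - eps) & (u_mm <= u1 * 10.0 * factor + eps)
            sv = (v_mm >= v0 * 10.0 * factor - eps) & (v_mm <= v1 * 10.0 * factor + eps)
            mask |= sv[:, None] & su[None, :]
    if not mask.any():
        raise ValueError(f"beam {beam.name}: empty CIAO, no ROI to analyze")
    if dose_threshold is not None and dose_plane is not None:
        vals = dose_plane.values
        cutoff = dose_threshold * np.nanmax(vals)
        mask &= np.nan_to_num(vals, nan=-np.inf) >= cutoff
    return CiaoMask(mask=mask, source=beam.name, exclusions_applied=[])


def subtract_roi(mask: CiaoMask, contour_mm, spec: PlaneSpec, name: str = "exclusion") -> CiaoMask:
    """Remove pixels inside a planar exclusion contour from the CIAO.

    ``contour_mm`` is a sequence of (u, v) vertices in the plane frame (mm);
    an empty contour is the identity.  Removing everything raises, since an
    empty ROI cannot be analyzed.  Applying the same contour twice is
    idempotent.
    """
    contour_mm = np.asarray(contour_mm, dtype=float).reshape(-1, 2)
    if contour_mm.shape[0] < 3:
        return CiaoMask(
            mask=mask.mask.copy(),
            source=mask.source,
            exclusions_applied=list(mask.exclusions_applied),
        )
    poly = Polygon(contour_mm)
    u_mm, v_mm = spec.coords()
    uu, vv = np.meshgrid(u_mm, v_mm)
    inside = shapely.contains_xy(poly, uu.ravel(), vv.ravel()).reshape(uu.shape)
    boundary = shapely.intersects_xy(poly.exterior, uu.ravel(), vv.ravel()).reshape(uu.shape)
    new = mask.mask & ~(inside | boundary)
    if not new.any():
        raise ValueError("exclusion contour removes the entire ROI")
    return CiaoMask(
        mask=new,
        source=mask.source,
        exclusions_applied=list(mask.exclusions_applied) + [name],
    )
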