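"""BEV-parallel plane extraction, B-field shift approximation, attenuation.

The analysis plane for a beam is perpendicular to the beam central axis and
passes through the plan reference point.  Its in-plane frame is fixed by the
1.5-T main field, which lies along the patient superior-inferior axis:

* ``axis_v`` (BEV-Y of the conventional-TPS view) is perpendicular to both
  the B-field axis and the beam axis — the leaf-stacking/lateral direction
  and the direction of the 2-mm Lorentz shift;
* ``axis_u`` completes the right-handed frame (u x v = normal) and is the
  leaf-travel direction, parallel to the S-I axis at gantry 0.

The magnetic field curls secondary electrons so the transverse dose profile
is, to first order, rigidly translated along v; the second calculation has
no B-field, so the reference (Monte-Carlo-side) plane is translated back
before the comparison.  The translation is applied to extracted planes only
and never persisted to the stored dose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .rt_model import BeamRecord, DoseGrid

__all__ = [
    "PlaneSpec",
    "DosePlane",
    "CorrectionConfig",
    "beam_unit_vectors",
    "bev_plane_for_beam",
    "sample_plane",
    "sample_grid_point",
    "shift_plane",
    "classify_posterior",
    "apply_attenuation",
    "B_AXIS",
]

#: Main-field axis in the DICOM patient frame (superior-inferior).
B_AXIS = np.array([0.0, 0.0, 1.0])


def beam_unit_vectors(gantry_angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, normal) for a coplanar beam in the DICOM patient frame.

    Gantry 0 has the source anterior; the central-axis direction (source ->
    isocenter) is ``normal``.  ``v = normal x B_axis`` normalized, ``u = v x
    normal``; the triple is right-handed with ``u x v = normal``.
    """
    g = np.deg2rad(gantry_angle_deg)
    source_dir = np.array([np.sin(g), -np.cos(g), 0.0])  # iso -> source
    normal = -source_dir
    v = np.cross(normal, B_AXIS)
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("beam axis parallel to the B-field axis: BEV frame undefined")
    v = v / nv
    u = np.cross(v, normal)
    return u, v, normal


@dataclass(frozen=True)
class PlaneSpec:
    """Sampling lattice of a BEV-parallel plane.

    ``origin`` (mm, patient frame) is the lattice center; samples lie at
    ``origin + u_mm * axis_u + v_mm * axis_v`` with ``u_mm, v_mm`` symmetric
    about zero.  Arrays over the plane are indexed ``values[iv, iu]``.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    normal: np.ndarray
    spacing: float  # mm
    extent: tuple[int, int]  # (nu, nv)

    def __post_init__(self):
        for name in ("origin", "axis_u", "axis_v", "normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.spacing <= 0:
            raise ValueError("plane spacing must be positive")
        gram = np.array([self.axis_u, self.axis_v, self.normal])
        if not np.allclose(gram @ gram.T, np.eye(3), atol=1e-9):
            raise ValueError("plane axes must be orthonormal")
        if not np.allclose(np.cross(self.axis_u, self.axis_v), self.normal, atol=1e-9):
            raise ValueError("plane frame must satisfy u x v = normal")

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane sample coordinates (u_mm, v_mm), each 1D."""
        nu, nv = self.extent
        u = (np.arange(nu) - (nu - 1) / 2.0) * self.spacing
        v = (np.arange(nv) - (nv - 1) / 2.0) * self.spacing
        return u, v

    def points(self) -> np.ndarray:
        """Patient-frame positions of every sample, shape (nv, nu, 3)."""
        u, v = self.coords()
        uu, vv = np.meshgrid(u, v)  # (nv, nu)
        return (
            self.origin[None, None, :]
            + uu[..., None] * self.axis_u[None, None, :]
            + vv[..., None] * self.axis_v[None, None, :]
        )


@dataclass
class DosePlane:
    """2D dose image (Gy) on a plane lattice; invalid samples are NaN."""

    values: np.ndarray
    spec: PlaneSpec
    role: str = "reference"  # or "evaluated"
    shift_applied_mm: float = 0.0
    attenuation_applied: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        nu, nv = self.spec.extent
        if self.values.shape != (nv, nu):
            raise ValueError("plane values shape must match spec extent (nv, nu)")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class CorrectionConfig:
    """B-field shift and RF-coil attenuation corrections.

    ``bfield_shift_mm`` is the shift magnitude (2 mm from profile
    commissioning); ``shift_sign`` fixes the direction along +v actually
    applied to the reference plane (sign * magnitude).  The posterior
    receive coil attenuates beams traversing it by ~2.2 % (factor 0.978);
    the anterior coil (~0.4 %) is ignored.  A beam counts as posterior when
    its gantry angle lies in ``posterior_gantry_range`` (closed interval,
    modulo 360).
    """

    bfield_shift_mm: float = 2.0
    shift_sign: float = -1.0
    posterior_coil_factor: float = 0.978
    anterior_coil_factor: float = 1.0
    posterior_gantry_range: tuple[float, float] = (100.0, 260.0)

    def __post_init__(self):
        for f in (self.posterior_coil_factor, self.anterior_coil_factor):
            if not 0 < f <= 1:
                raise ValueError("attenuation factors must lie in (0, 1]")
        if not np.isfinite(self.bfield_shift_mm):
            raise ValueError("bfield_shift_mm must be finite")

    @property
    def signed_shift_mm(self) -> float:
        return self.shift_sign * self.bfield_shift_mm


def bev_plane_for_beam(
    beam: BeamRecord,
    reference_point,
    spacing: float,
    extent: tuple[int, int],
) -> PlaneSpec:
    """Plane through ``reference_point`` perpendicular to the beam axis."""
    u, v, normal = beam_unit_vectors(beam.gantry_angle)
    return PlaneSpec(
        origin=np.asarray(reference_point, dtype=float),
        axis_u=u,
        axis_v=v,
        normal=normal,
        spacing=float(spacing),
        extent=tuple(extent),
    )


def _grid_index_coords(grid: DoseGrid, points: np.ndarray) -> np.ndarray:
    """Fractional (iz, iy, ix) index coordinates of patient-frame points."""
    rel = points.reshape(-1, 3) - grid.origin[None, :]
    local = rel @ grid.orientation  # components along grid axes (x, y, z)
    idx = local / grid.spacing[None, :]
    return idx[:, ::-1].T  # (3, n) ordered (iz, iy, ix)


def sample_plane(grid: DoseGrid, spec: PlaneSpec, role: str = "reference") -> DosePlane:
    """Trilinear resampling of the grid on the plane lattice.

    Samples outside the grid are NaN (excluded from any ROI), never
    zero-filled; a plane wholly outside the grid raises.
    """
    pts = spec.points()
    coords = _grid_index_coords(grid, pts)
    vals = ndimage.map_coordinates(
        grid.values, coords, order=1, mode="constant", cval=np.nan
    ).reshape(pts.shape[:2])
    if not np.any(np.isfinite(vals)):
        raise ValueError("plane lies wholly outside the dose grid")
    return DosePlane(values=vals, spec=spec, role=role)


def sample_grid_point(grid: DoseGrid, point) -> float:
    """Trilinear dose (Gy) at one patient-frame point; NaN if outside."""
    coords = _grid_index_coords(grid, np.asarray(point, float).reshape(1, 3))
    return float(
        ndimage.map_coordinates(grid.values, coords, order=1, mode="constant", cval=np.nan)[0]
    )


def shift_plane(plane: DosePlane, shift_mm: float) -> DosePlane:
    """Translate the plane values by ``shift_mm`` along +v (linear
    interpolation); the trailing margin becomes invalid (NaN)."""
    nv = plane.values.shape[0]
    if abs(shift_mm) >= nv * plane.spec.spacing:
        raise ValueError("shift exceeds the plane extent")
    if shift_mm == 0.0:
        return replace(plane, values=plane.values.copy())
    # value at v comes from v - shift: features move toward +v
    shifted = ndimage.shift(
        plane.values,
        (shift_mm / plane.spec.spacing, 0.0),
        order=1,
        mode="constant",
        cval=np.nan,
    )
    return replace(
        plane, values=shifted, shift_applied_mm=plane.shift_applied_mm + shift_mm
    )


def classify_posterior(beam: BeamRecord, cfg: CorrectionConfig) -> bool:
    """True iff the gantry angle lies in the posterior interval (closed,
    interval arithmetic modulo 360)."""
    lo, hi = cfg.posterior_gantry_range
    g = beam.gantry_angle % 360.0
    lo, hi = lo % 360.0, hi % 360.0
    if lo <= hi:
        return lo <= g <= hi
    return g >= lo or g <= hi


def apply_attenuation(obj, factor: float):
    """Multiply every dose value by ``factor`` (a transmission in (0, 1]);
    the applied factor is recorded on the returned copy."""
    if factor <= 0:
        raise ValueError("attenuation factor must be positive")
    if isinstance(obj, DosePlane):
        return replace(
            obj,
            values=obj.values * factor,
            attenuation_applied=obj.attenuation_applied * factor,
        )
    if isinstance(obj, DoseGrid):
        out = DoseGrid(
            values=obj.values * factor,
            origin=obj.origin.copy(),
            spacing=obj.spacing.copy(),
            orientation=obj.orientation.copy(),
            summation=obj.summation,
            source_engine=obj.source_engine,
            beam_number=obj.beam_number,
        )
        return out
    raise TypeError(f"cannot attenuate {type(obj).__name__}")
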