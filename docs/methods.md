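# Methods

`imucheck` implements an independent monitor-unit (MU) second check for
online adaptive plans delivered on a high-field (1.5-T) MR-Linac with a
143.5-cm source-to-axis distance (SAD). The clinical pattern it models: the
Monte-Carlo-based planning system computes the treatment dose with the
magnetic field; a second, conventional 100-cm-SAD planning system
recalculates the plan with fixed MU and no field model; the two per-beam
dose distributions are compared by 2D gamma analysis on a beam's-eye-view
(BEV) parallel plane. Because the two commercial dose engines cannot ship
with a desk-scale package, a deliberately simple synthetic engine generates
both sides of the comparison, isolating the pipeline's own transformations
and corrections as the quantities under test.

## Plan dialect transformation

Two RT Plan dialects are modeled. The `monaco` dialect (native MR-Linac
export) has SAD 143.5 cm, collimator fixed at 0°, MLC positions in the
DICOM beam-limiting-device type `MLCY`, no moving X jaws and a fixed 22-cm
superior–inferior extent (leaf overtravel limited to ±11 cm). The `eclipse`
dialect (conventional TPS) has SAD 100 cm, collimator 90°, MLC positions in
`MLCX` and explicit asymmetric jaws. Dialect detection is by the MLC tag
name with the SAD as confirmation; disagreement raises, never a silent
guess.

Conversion applies, per beam:

1. **SAD rescaling.** All collimating positions are multiplied by
   100/143.5 (divided by 1.435), leaving the projected aperture in the
   original BEV plane unchanged. The beam switches to the extended-SSD
   technique: the nominal SAD becomes 100 cm while the physical
   source-to-isocenter distance (143.5 cm) is preserved, so the source
   position in the patient frame is identical.
2. **Energy relabel.** `7MV-FFF` → `6MV-FFF` (a nominal label change; the
   spectrum is not modeled).
3. **Axis interchange.** `MLCY` → `MLCX` with the collimator angle set to
   90°; the rotation exactly compensates the relabeling, so the projected
   aperture is invariant (verified by rasterization to 10⁻⁹ mm). New X jaws
   are the envelope of *open* leaf positions plus a 5-mm margin, clipped to
   the physical ±7.67-cm projection of the ±11-cm overtravel; a fixed
   ±7.67-cm mode is also available. The fixed 22-cm extent maps to the Y
   jaws, scaled to the 100-cm plane.

Numerical conventions: all lengths internally in cm at the owning dialect's
isocenter-projection plane (DICOM mm converted at the boundary); a leaf
pair counts as open when its gap exceeds 0.05 cm at the 143.5-cm plane,
rescaled with the geometry so "open" is projection-invariant; parked closed
pairs never drive the jaw envelope. The jaw rule is applied per beam
(envelope over control points) because the target dialect expects static
jaws. The 5-mm margin is interpreted at the 100-cm plane, where the rule is
stated after rescaling. MU are never modified.

The MLC geometry is 31 pairs of 7-mm projected leaves (21.7-cm stacking
span). A 22-cm span is not an integer number of 7-mm leaves; the leaf
width was kept exact and the pair count chosen to fill the field.

## Analysis frame and plane extraction

The main field lies along the patient superior–inferior (S–I) axis. For a
coplanar beam at gantry angle g the analysis frame is: `normal` = central
axis direction; `v` = normal × B̂ (normalized) — in-plane, always
perpendicular to both the field axis and the beam axis, the
leaf-stacking/lateral direction and the direction of the Lorentz profile
shift; `u` = v × normal — the leaf-travel direction, parallel to S–I at
gantry 0. The analysis plane passes through the plan reference point,
perpendicular to the beam axis, sampled at 1 mm (default) over the CIAO
bounding box plus a 2-cm margin. Plane samples are trilinear
interpolations of the 3D grid; samples outside the grid are marked invalid
(NaN) and excluded from the ROI rather than zero-filled, which would
fabricate failures at plane edges.

## B-field shift and attenuation corrections

The field curls secondary electrons so the transverse profile is, to first
order, rigidly translated along v. The reference (field-aware) plane is
translated back by the commissioned magnitude (2 mm) before comparison;
the sign convention is configuration-exposed (`shift_sign`, default −1,
meaning the correction undoes a +v deflection). The shift is applied only
to the extracted plane, never persisted to stored dose. Known first-order
limit, reproduced by the toy engine: where the entry surface is oblique to
the beam, depth attenuation has a gradient along v and a rigid shift
leaves a residual of order μ·s (≈1 % for μ = 0.05 cm⁻¹ and s = 2 mm);
the electron return effect at tissue–air interfaces is entirely outside
the approximation.

The posterior receive coil attenuates beams traversing it by ≈2.2 %; the
second calculation does not model it, so evaluated-side doses of posterior
beams are multiplied by 0.978. The anterior coil (≈0.4 %) is ignored.
"Posterior" is gantry ∈ [100°, 260°] (closed, modulo 360), configurable —
beams in that range traverse the couch and coil. The couch itself is
present in both calculations (its contours transfer to the second system)
and therefore needs no correction; the toy engine gives both sides the
couch slab. The 2.2 % correction is a uniform scalar on the whole beam
dose.

## CIAO region of interest

The complete irradiated area outline is the union over control points of
the open aperture (leaf rectangles ∩ jaw window), projected to the
analysis plane by the divergence factor (source-to-plane distance over
definition-plane distance) and rasterized by pixel-center containment with
ties counted inside (deterministic). No dose threshold is applied inside
the CIAO by default. Planar exclusion contours (e.g. an airway) can be
subtracted; exclusion is idempotent and removing the whole ROI is an
error.

## Gamma analysis

For reference pixel r, γ(r) = min over evaluated positions e of
√(|e−r|²/δ² + (Dₑ(e)−Dᵣ(r))²/ΔD²), with δ the distance-to-agreement (DTA)
and ΔD the dose criterion as a percent of the normalization dose — the
maximum of the reference plane over the ROI (a global, percent-of-maximum
criterion). Criteria sets 3 %/3 mm (primary, verdict at a 95 % pass-rate
threshold) and 3 %/2 mm (informational) are the defaults.

`gamma_map` minimizes over a candidate-offset lattice of pitch
`interp_step` (default DTA/10) out to `search_radius` (default 3·DTA),
with bilinear interpolation of the evaluated plane. Offsets are processed
in order of increasing radius with an active-set early exit: a pixel
whose current best γ² is below the spatial term alone cannot improve, and
the loop stops when that holds for every ROI pixel. γ is capped at
search_radius/DTA. Pixels whose search neighborhood is less than half
valid are dropped from the ROI with a warning. The pass condition is
γ ≤ 1 + 10⁻⁹.

`gamma_brute_force` is the independent oracle: exhaustive search over a
dense lattice covering the whole plane (default pitch `interp_step`/2,
overridable), no radius shortcut, no early exit, guarded to ≤ 64×64
planes. Equivalence checks run both routes over the *same* candidate
lattice (the oracle's `step_mm` set to `interp_step`, chosen to divide the
pixel pitch so the lattices align); two different candidate sets cannot
agree to 10⁻⁶ on generic smooth fields, while the shared-lattice check
still exercises everything that distinguishes the optimized path from the
naive one. Refinement monotonicity (halving the oracle pitch never
increases γ) is tested separately.

## Synthetic engine and study conditions

Per beam, D(p) = MU · C · (SAD/w)² · exp(−μ·depth) · F(t,s): inverse
square along the axis distance w, water-equivalent depth from ray–box
entry, and an isocenter-plane fluence F = control-point-weighted aperture
raster convolved with a Gaussian penumbra (σ = 3 mm at isocenter, scaling
with divergence automatically because F is evaluated in BEV coordinates),
multiplied by a linear flattening-filter-free off-axis falloff
(1.5 %/cm). C is fixed by the 1 cGy/MU calibration at 138.5-cm SSD and
5.0-cm depth. Slabs (couch: 2 cm, transmission ≈0.970; posterior coil:
1 cm, transmission 0.978) attenuate rays crossing them with their
normal-incidence Beer–Lambert transmission — a thin flat attenuator, the
same idealization the flat 2.2 % correction makes, so the correction can
cancel it exactly. Optional Gaussian noise (percent of beam maximum)
emulates Monte-Carlo statistical noise.

The reference side runs with the 2-mm profile shift and the coil slab;
the evaluated side with neither (no field model, coil invisible to it).
Both sides share the engine otherwise, so a matched case passes near 100 %
by construction and the pipeline's corrections are the only
discriminators. Study conditions: 15 beams per plan, gantry angles spread
over the full circle, staircase apertures of 3–6 cm, 1–3 segments per
beam, 1 % noise, 2-mm dose grids on a 20-cm phantom. The engine does not
model scatter, heterogeneity beyond slabs, leaf transmission or the
electron return effect; passing tests therefore demonstrate the
pipeline's transformations, not commercial-engine dosimetry.

Mismatch injection perturbs the evaluated side only: MU scaling errors,
whole-bank leaf shifts (dose recomputed), a wrong shift sign, or a
missing coil correction; every perturbation is recorded in the case
manifest. The sensitivity design generates 94 beams across seven plans
with 18 mismatches (alternating MU errors of 6–10 % and leaf shifts of
5–6 mm — magnitudes chosen so the 95 % threshold separates the
populations on this engine, and recorded per case). Expected behavior,
verified by the acceptance suite: all 18 mismatched beams fail, ≥90 % of
matched beams pass, and the shifted comparison strictly beats the
unshifted one on every beam at 3 %/2 mm (at 3 %/3 mm a rigid 2-mm offset
lies strictly inside the DTA ball, so the unshifted comparison saturates
at 100 % and no strict gap can exist — the tighter criterion is the
discriminating one).

## Contingency analysis

Agreement between two QA modalities' pass/fail verdicts is summarized by
a 2×2 table, the Pearson contingency coefficient √(χ²/(χ²+n)) without
continuity correction (bounded by √½ for 2×2 tables), and a two-sided
Fisher exact p-value. Degenerate tables (one modality all-pass or
all-fail) yield coefficient 0 with a warning.

## Known limitations

- The lateral-shift approximation ignores the electron return effect and
  any depth dependence of the shift.
- 2D planar gamma only; no 3D gamma or DVH-based comparison.
- The toy engine's simplicity means absolute pass rates here say nothing
  about commercial-engine agreement on patients; only the relative,
  directional properties (criteria ordering, shift gain, mismatch
  separation) transfer.
- Collimator angles other than the 0° → 90° conversion case are
  unsupported.
- Technique and physical source distance are carried in `BeamDescription`
  (`TECHNIQUE:...;SRCDIST:...`), a documented convention of this writer,
  because no standard RT Plan attribute holds them.
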