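# imucheck

Independent monitor-unit (MU) second check for online adaptive plans on a
high-field (1.5-T) MR-Linac.

Adaptive MR-guided radiotherapy creates a new plan at every fraction, and
patient safety requires an independent verification of each one before
delivery. `imucheck` implements the full second-check chain for medical
physicists: it transforms the MR-Linac planning system's DICOM RT Plan
dialect (SAD 143.5 cm, collimator 0°, MLC in tag `MLCY`, no X jaws) into a
conventional-TPS dialect (SAD 100 cm, collimator 90°, `MLCX`, explicit
jaws), then compares the per-beam 3D dose distributions from the two
systems by 2D gamma analysis on a beam's-eye-view (BEV) parallel plane
through the plan reference point, restricted to the beam's complete
irradiated area outline (CIAO).

Two physics corrections bridge the systems: the 1.5-T field deflects
secondary electrons so the transverse profile is approximately rigidly
shifted — the reference plane is translated 2 mm along the BEV axis
perpendicular to both the field and the beam before comparison — and the
posterior MR receive coil, invisible to the second calculation, attenuates
posterior beams by 2.2 % (evaluated dose × 0.978 for gantry angles in
[100°, 260°]).

The gamma index at reference pixel r is

    γ(r) = min over e of sqrt( |e − r|² / δ²  +  (Dₑ(e) − Dᵣ(r))² / ΔD² )

with δ the distance-to-agreement (3 or 2 mm) and ΔD = 3 % of the maximum
reference dose over the ROI; a beam passes when ≥95 % of ROI pixels have
γ ≤ 1. An exhaustive brute-force gamma oracle, a synthetic divergent-beam
dose engine (so the whole chain runs without the commercial dose engines),
deliberate mismatch injection for sensitivity studies, and a 2×2
contingency analysis between QA modalities complete the package.

## Worked example

```python
import imucheck as ic
from imucheck.synth_fixtures import make_synthetic_case, inject_mismatch

# a matched 3-beam case: reference doses with the B-field shift and coil,
# evaluated doses without either (as the second calculation would see it)
case = make_synthetic_case("demo", seed=17, n_beams=3, noise_sd_pct=0.5)
# perturb the evaluated side of beam 2 with an 8 % MU error
case = inject_mismatch(case, "mu_error", 0.08, seed=2, beam_numbers=[2])

records, summary = ic.run_imu_case(case)
print(ic.render_report(records, summary, None))
```

prints

```
Independent MU check — per-beam gamma report
============================================================
 beam name  gantry posterior  3%/3mm  3%/2mm verdict
    1  B01   101.4       yes   100.0   100.0    PASS
    2  B02   221.4       yes    57.0    49.1   FAIL*
    3  B03   341.4        no   100.0   100.0    PASS
------------------------------------------------------------
primary criteria: 3%/3mm at threshold 95%
plan mean/min/max/sd of per-beam pass rate: 85.7 / 57.0 / 100.0 / 20.3 %
plan verdict: FAIL (1 beam(s) below threshold)

configuration:
  bfield shift: -2 mm along BEV-v (applied to the reference plane)
  posterior coil factor: 0.978 for gantry in (100.0, 260.0)
  plane spacing: 1.0 mm; ROI: beam CIAO
  criteria evaluated: 3%/3mm, 3%/2mm
```

The two matched beams pass 100 % at both criteria sets; the injected 8 %
MU error collapses beam 2's pass rate to 57 %, far below the 95 %
threshold, and fails the plan — exactly the behavior a second check
exists to produce.
The same pipeline runs from files (`ic.run_imu(plan_path, ref_dir,
eval_dir)`) and from the command line:

```bash
imucheck simulate ./case --beams 15 --seed 1
imucheck check ./case/case_rtplan.dcm ./case/reference ./case/evaluated --report report.txt
imucheck convert monaco_plan.dcm eclipse_plan.dcm
```

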