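# rtqa

Patient-specific delivery-verification QA for radiotherapy (IMRT/VMAT),
implemented as a plain scientific-Python library with a CLI.

When an intensity-modulated plan is delivered, the dose the patient actually
receives can deviate from the treatment-planning-system calculation through
setup shifts, output-calibration errors, penumbra blurring, and measurement
noise. This package quantifies such deviations the way a physics QA program
does:

- **Gamma-index analysis** — the standard combined dose-difference /
  distance-to-agreement comparison (default 3% / 3 mm, low-dose threshold
  20 cGy), for 2D detector-array planes and full 3D dose grids, globally and
  restricted to individual anatomical structures. A point passes when
  γ ≤ 1.
- **DVH metrics and deviations** — exact (unbinned) cumulative dose-volume
  histograms, point doses D2%/D50%/D95%/D98%/Dmean, volumes V100%/V95%,
  homogeneity index HI = (D2% − D98%)/D50%, conformity index
  CI = (PTV95%/PTV)·(PTV95%/V95%), plan-vs-delivery relative deviations, and
  across-case one-sample t-tests.
- **Angular response correction** — plane-parallel ion-chamber arrays
  under-respond when the beam arrives near-laterally (gantry 90°/270°). A
  correction-factor table measured for the central chamber over a calibration
  sweep (5° steps, refined to 1° near the lateral angles) is applied per
  detector at each detector's own incident angle
  φ = atan2(d + SAD·sinθ, SAD·cosθ), where d is the detector's in-plane
  offset from the rotation axis.
- **Synthetic ground truth** — a QA-phantom-sized dose grid, a
  nasopharynx-like structure template with nested targets
  (PTVnx ⊂ PTV1 ⊂ PTV2) and organs at risk, an analytic conformal plan
  (Gaussian-blurred prescription-weighted target indicators), seeded delivery
  perturbations, a 32×32 / 7.62 mm-pitch / 1020-active-element detector-array
  sampler, and a smooth angular-response model — so every algorithm can be
  validated against known answers.
- **File formats** — DICOM RT Dose and RT Structure Set (via pydicom), an
  ASCII planar-dose format, run-length-encoded structure masks, and
  correction-table CSVs. The internal dose unit is cGy throughout.

See `docs/methods.md` for the models, numerical choices, and limitations.

## Worked example

Simulate a plan on a phantom, perturb the delivery (3 mm lateral shift, +2%
output, 0.3% noise), and verify it:

```python
from rtqa import (GammaCriteria, PerturbationSpec, compute_gamma, pass_rate,
                  default_prescription, make_npc_structures, make_phantom,
                  make_planned_dose, perturb_dose, cumulative_dvh,
                  dose_at_volume, relative_deviation)

grid = make_phantom(spacing_mm=4.0, dims_cm=(26.0, 26.0, 14.0))
structures = make_npc_structures(grid, seed=1)
prescription = default_prescription()          # 7000/6600/6000 cGy
plan = make_planned_dose(structures, prescription)

spec = PerturbationSpec(shift_mm=(3.0, 0.0, 0.0), scale=1.02,
                        noise_pct=0.3, seed=11)
delivered = perturb_dose(plan, spec, prescription.normalization)

criteria = GammaCriteria(dose_tolerance=3.0, dta=3.0,
                         normalization="prescription",
                         low_dose_threshold=20.0)
result = compute_gamma(plan, delivered, criteria,
                       normalization_dose=prescription.normalization)
print(f"global pass rate: {100 * pass_rate(result):.2f}%")
for name in ("PTVnx", "PTV1", "PTV2", "Brainstem"):
    p = pass_rate(result, structures[name], structure_name=name)
    print(f"{name:>9} pass rate: {100 * p:.2f}%")

c_plan = cumulative_dvh(plan, structures["PTVnx"])
c_rdd = cumulative_dvh(delivered, structures["PTVnx"])
d95_plan = dose_at_volume(c_plan, 0.95)
d95_rdd = dose_at_volume(c_rdd, 0.95)
print(f"PTVnx D95%: planned {d95_plan:.1f} cGy, delivered {d95_rdd:.1f} cGy "
      f"({relative_deviation(d95_rdd, d95_plan):+.2f}%)")
```

Output:

```
global pass rate: 96.79%
    PTVnx pass rate: 95.87%
     PTV1 pass rate: 96.66%
     PTV2 pass rate: 97.28%
Brainstem pass rate: 100.00%
PTVnx D95%: planned 5940.7 cGy, delivered 5929.3 cGy (-0.19%)
```

The shifted, hotter delivery fails a few percent of points in the
steep-gradient target regions while the distant brainstem is unaffected; the
D95% deviation stays small because the +2% output partly compensates the
shift at the target periphery.

## Command line

The `rtqa` entry point wraps the library:

```sh
rtqa simulate -o fixtures/           # generate a scenario's files on disk
rtqa gamma2d ref_plane.txt meas_plane.txt
rtqa gamma3d plan.dcm delivered.dcm --structures masks.txt
rtqa dvh plan.dcm masks.txt --structure PTVnx
rtqa metrics plan.dcm delivered.dcm masks.txt --prescription PTVnx=7000
rtqa angcorr build calibration.csv -o table.csv
rtqa angcorr apply meas_plane.txt table.csv -o corrected.txt
rtqa report -o report/               # cases.csv + summary.csv
```

`simulate` and `report` accept a YAML scenario config (`-c`); omitted keys
fall back to the built-in default scenario.

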