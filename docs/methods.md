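# Methods

This document records the mathematical models, the numerical choices, and
the known limitations of the package. The internal dose unit is cGy
everywhere; geometry is in mm.

## Dose representations

`DoseGrid` holds a 3D dose array in `(x, y, z)` axis order with uniform
per-axis spacing and a voxel-center origin: voxel `(i, j, k)` is centered at
`origin + (i·sx, j·sy, k·sz)`. `PlanarDose` is the 2D analogue with an
`active` mask marking physical detector elements (for a MatriXX-class array:
a 32×32 lattice, 7.62 mm pitch, four corner elements absent, 1020 active).
Doses must be finite and non-negative.

Contours are rasterized with an even-odd (ray-casting) rule, so a contour
nested inside another carves a hole; each polygon is assigned to the nearest
grid z-layer. Resampling between grids is trilinear, with points outside the
source extent reported in an `inside` mask.

## Gamma index

For reference dose `Dr` at point `r` and evaluated dose `De`, with dose
tolerance `ΔD` (percent of a normalization dose, converted to cGy) and
distance-to-agreement `dta` (mm):

```
γ(r) = min over r'  sqrt( |r' − r|² / dta²  +  (De(r') − Dr(r))² / ΔD² )
```

A point passes when γ ≤ 1 (boundary inclusive). Normalization modes:

- `global_reference_max` — ΔD% of the reference maximum (planar default);
- `prescription` — ΔD% of an explicitly supplied dose (used for 3D
  comparisons against the prescription normalization);
- `local` — ΔD% of each reference point's own dose.

The low-dose threshold (default 20 cGy) excludes points whose *reference*
dose is not strictly above the threshold; it applies to the global pass rate
only. Structure-restricted pass rates deliberately count every valid point
inside the structure mask, including sub-threshold ones, so cold organs are
scored over their full volume.

### Search algorithm

The minimization is over a discrete displacement lattice: step
`dta/10` (0.3 mm at 3 mm DTA), radius `3·dta`, both overridable. Offsets are
sorted by distance and processed in shells; once the distance term alone
exceeds the best γ² found so far, no further shell can improve any remaining
point and the search terminates. The evaluated dose is interpolated
(bi/trilinearly) at displaced positions; displacements that leave the
evaluated extent are skipped. Work is chunked over points × offsets to bound
memory.

### Discretization bound

Quantizing the displacement to a lattice of step `h` can overestimate γ by
at most

```
L · h · sqrt(dim) / 2,     L = sqrt( 1/dta² + (G/ΔD)² )
```

where `G` is the maximum dose-gradient magnitude of the evaluated field
(from forward differences) — the γ integrand is `L`-Lipschitz in the
displacement, and the nearest lattice point is within `h·sqrt(dim)/2` of the
continuous optimum. `lattice_bound` computes this bound; the exhaustive
`gamma_oracle` (a plain per-point scan on a finer lattice, refusing inputs
above 64 points per axis) is used in the tests to verify the production
search agrees within it. Because the fine lattice refines the coarse one,
the production result can never fall below the oracle's.

Two closed forms anchor the implementation: a uniform +3% offset under a 3%
criterion gives γ = 1 everywhere, and a 3 mm shift of a 1 %/mm linear
gradient gives interior γ = √2/2 (the optimum displacement, 1.5 mm, lies on
the default lattice, so the value is attained exactly).

## DVH metrics

DVH curves are exact voxel lists, not histograms: the structure's voxel
doses are sorted, and the cumulative volume fraction at dose `d` counts
voxels with dose ≥ `d` (boundary inclusive). Dx% uses order statistics: the
sorted-descending doses are placed at volume positions `(i − 0.5)/n` and
linearly interpolated, clamped at the extremes (so D100% is the minimum
voxel dose). Vd counts voxels exactly; `percent=True` thresholds at the
given percentage of the prescription.

- HI = (D2% − D98%) / D50% — 0 for a perfectly uniform target dose.
- CI = (PTV95% / PTV) · (PTV95% / V95%), where PTV95% is the target volume
  covered by ≥ 95% of the prescription and V95% the total volume at that
  level — 1 for perfect conformity, and bounded by both coverage and
  selectivity. When nothing reaches the 95% level the CI is defined as 0
  (with a warning).

Relative deviations are `100·(delivered − planned)/planned`; a zero planned
value is an error, and the report layer records such entries as undefined
rather than fabricating a number. Across-case summaries use the classical
one-sample two-sided t-test (`t = mean/(s/√n)`, `df = n − 1`). Degenerate
samples follow explicit conventions: all-zero deviations give p = 1 (no
evidence of deviation); zero variance around a nonzero mean is flagged
`degenerate` with p = NaN and a warning, since the t-statistic is undefined.

## Angular response correction

A plane-parallel chamber's response depends on the beam's incident angle,
dipping near lateral incidence. For a detector at signed in-plane offset `d`
(mm) from the rotation axis and gantry angle θ,

```
φ = atan2(d + SAD·sin θ, SAD·cos θ)   mapped to [0°, 360°)
```

The two-argument arctangent makes the quadrant explicit, including the
degenerate lateral case (cos θ = 0). Offsets along the rotation axis do not
change incidence. Correction factors are measured for the central chamber
over a calibration sweep — 5° steps over [0°, 360°), refined to 1° steps
within ±5° of 90° and 270° where the response varies fastest — as
`[calc(θ)/meas(θ)] / [calc(0)/meas(0)]`, i.e. ratio-normalized so the
0° factor is exactly 1. Lookup is periodic linear interpolation (360° wraps
to 0°), and application multiplies each detector by the factor at its own φ.
With the synthetic response model (Gaussian dips of amplitude 0.2 and width
10° plus a 1% two-cycle ripple), table-based correction recovers the true
dose within 0.5% at every active detector for arbitrary gantry angles; the
residual is pure interpolation error of the response curve between
calibration samples.

## Synthetic data generator

The generator provides ground truth with controlled, interpretable errors.
Its defaults are study conditions, chosen a priori:

- **Phantom**: a box of 31.4 × 34 × 22 cm (a MULTICube-class QA phantom) on
  a 3 mm grid by default; voxel counts are `ceil(extent/spacing)` and the
  grid is centered on the origin.
- **Structure template**: PTVnx is an ellipsoid (semi-axes 25/20/20 mm);
  PTV1 and PTV2 are exact Euclidean dilations of it by 5 and 10 mm (via the
  distance transform of the complement with physical sampling), which
  guarantees PTVnx ⊆ PTV1 ⊆ PTV2 voxelwise. Brainstem and spinal cord are
  z-cylinders posterior to the targets, the optic nerves are thin
  x-cylinders meeting a small chiasm, and the parotids are lateral
  ellipsoids. The organs at risk are placed close enough to the target
  complex that their reported metrics (serial-organ D2%, parotid Dmean) sit
  on the dose falloff rather than in numerical noise.
- **Planned dose**: the voxelwise maximum over targets of
  `prescription × GaussianBlur(indicator, σ = 4 mm)`. Inside a large target
  the blurred indicator saturates, so the dose approaches the prescription;
  outside, the falloff is Gaussian-smooth, mimicking a penumbra.
- **Perturbations** are applied in a fixed order — rigid shift (trilinear),
  global output scale, extra penumbra blur, seeded additive Gaussian noise
  (a percentage of the normalization dose, clipped at zero) — so identical
  specs reproduce identical doses bit for bit.
- **Detector sampling** is bilinear at the array lattice; the angular
  response multiplies each detector by R(φ), with R renormalized so
  R(0°) = 1 exactly.

### Limitations

- The analytic plan has no scatter bath: far from the targets the planned
  dose is essentially zero, unlike a clinical plan's diffuse low-dose
  region. Relative DVH deviations for distant cold structures are therefore
  ill-conditioned (a tiny absolute change is a huge percentage), which is
  why the template keeps reported organs near the falloff and the report
  layer drops undefined entries.
- Dilation margins below the voxel pitch cannot grow a mask (no voxel
  center falls in the margin shell), so PTV1 would coincide with PTVnx on
  grids coarser than 5 mm; configurations are expected to keep
  spacing ≤ margin.
- The angular response model is smooth and symmetric; real chambers can
  show asymmetries that a measured table would capture but this generator
  does not produce.

## Verification batches and problem sizes

A scenario config describes one phantom, template, prescription
(7000/6600/6000 cGy three-level boost by default), gamma criteria, response
model, beam-angle set, and a case list. For each case the pipeline computes:

- **SGAC** (single-gantry-angle composite): the delivered isocenter plane
  sampled at the array, compared to the planned plane — all beams delivered
  at 0°, so no angular response error enters.
- **MGAC** (multi-gantry-angle composite): the same delivered plane split
  evenly over the planned beam angles, each frame degraded by the angular
  response at its gantry angle, then summed — scored both uncorrected and
  after table-based correction. By construction the corrected composite can
  only improve on the uncorrected one.
- **3D gamma** against the prescription normalization, globally (with the
  low-dose threshold) and per structure.
- **DVH/HI/CI deviations** per structure, summarized across cases with the
  t-test.

Planar comparisons normalize to the reference maximum; the 2D gamma search
uses a 0.3 mm step with a 9 mm radius, and the 3D search a 1 mm step (one
third of the default voxel size) with the same radius — accuracy/runtime
trade-offs covered by the documented lattice bound.

The default scenario runs the full 3 mm phantom (105 × 114 × 74 voxels).
The test suite and the evaluation script use a reduced configuration chosen
for desk-scale runtime: 4 mm spacing on a 26 × 26 × 14 cm box, the smallest
centered box that still contains the full detector array extent (236.2 mm)
in-plane while keeping every template structure on the grid and the voxel
pitch below the 5 mm dilation margin. A full batch at this size completes in
about a second; the complete test suite runs in well under a minute.
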