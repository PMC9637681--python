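# Methods

This note documents the models, parameters and numerical choices behind
`implantac`, and what the synthetic experiments do and do not show.

## Digital knee phantom

The phantom is a deterministic, parametric stand-in for a cadaver-style
validation experiment. On a 200 × 200 × 120 mm field (default grid
160 × 160 × 40 at 1.25 × 1.25 × 3 mm; the bundled experiment configuration
uses 128 × 128 × 40 at 1.5625 mm in-plane for speed) it contains:

- a limb: soft-tissue cylinder (radius 70 mm) with an adipose rim to 78 mm;
- femur and tibia (radius 14 mm) above and below a joint line;
- a knee implant: cobalt-chromium femoral component (condylar half-cylinder
  shell), cobalt-chromium tibial component (baseplate + stem) and a
  polyethylene insert slab between them;
- four tracer vials modelled as 10 mm diameter finite cylinders: a
  reference vial on the skin surface away from the implant, and anterior,
  mid and posterior vials around the joint. Default volumes/activities are
  the known values of the emulated experiment (1.52/1.53/1.56/1.57 mL,
  1.15/1.16/1.18/1.19 MBq).

Vials are cylinders rather than the conical laboratory vials because the
recovery-coefficient correction is parameterised by diameter only; a
cylinder keeps the 10 mm assumption exact. Each vial's voxel set is
**volume-matched**: voxels are ranked by signed distance outside the
analytic cylinder and exactly `round(volume / voxel_volume)` are kept, so
the realised volume is within half a voxel volume of the dispensed volume
(the digital analogue of checking a drawn segmentation against the known
tracer volume). The in-vial concentration is dispensed activity divided by
realised volume, so the activity image integrates exactly to the dispensed
activity. Vials whose target volume falls below `min_vial_voxels`
(default 10) voxels are rejected as unrealisable at the grid resolution.

The MR signal void is the set of voxels within `void_dilation_mm`
(default 4 mm — "slightly beyond the prosthesis boundary" is not a
published number, so it is configurable) of any metal voxel, computed with
an exact anisotropic Euclidean distance transform. Degraded labels mark
these voxels `void`; everything else is untouched. The polyethylene insert
ends up almost entirely inside the void, as it would in practice (it gives
no MR signal and sits between the metal components).

Geometry is fully deterministic; the configuration seed only feeds the
Poisson acquisition noise downstream.

## Attenuation maps

`mumap_from_labels` performs a pure per-material lookup (cm⁻¹ at 511 keV):
air 0, soft tissue 0.0927, adipose 0.0854, bone 0.13, polyethylene 0.079,
cobalt-chromium 0.72. Vial contents are water-equivalent and carry the
soft-tissue coefficient. Other metals (e.g. titanium) are supported by
supplying a user LAC in the material table. No interpolation is performed
anywhere: every output voxel carries a table value.

The three void strategies modify void voxels only:

- **original**: void → air (reproduces the uncorrected map's behaviour);
- **simple_tissue**: void → soft tissue;
- **model (accurate/alternative)**: void voxels covered by a rigidly placed
  component get that component's material (metal over polyethylene over
  soft tissue where placements overlap — components are solid, so metal
  wins); the rest of the void becomes soft tissue.

The label map is authoritative outside the void: all strategies leave
non-void voxels bit-identical to the truth map. The "alternative model" is
realised as a perturbed posterior-stabilised geometry (thicker condylar
shell with an intercondylar cam, wider baseplate, narrower insert) — the
method only requires a geometry plausibly different from the truth, not any
vendor's CAD file.

Rigid placement uses extrinsic x → y → z rotations (degrees) about the
grid centre followed by a translation (mm), resampled with
nearest-neighbour interpolation so the discrete label set survives. An
identity pose is exact; translation by a whole voxel pitch is an exact
index shift. A component whose in-grid footprint overlaps non-void anatomy
of a *different* material on more than 5 % of its voxels triggers a logged
warning (likely misregistration), mirroring what a human operator would
notice; the map is still produced.

## Acquisition model and reconstruction

The scanner is emulated at desk scale by a slice-wise 2-D parallel-beam
geometry: 105 views uniformly covering [0, π), detector pitch equal to the
in-plane voxel size, radial bins spanning the grid diagonal. Path lengths
through each pixel are exact chord lengths (Siddon-style sorted parametric
crossings), assembled into a sparse system matrix `P` shared by the
simulator and the reconstructor; an independent per-pixel box-clipping
integrator pins this matrix to 1e-6 relative accuracy in the tests.

Expected counts per line of response are

    ybar = s · exp(−∫ µ dl) · (P x)

with `x` the activity concentration (MBq/mL), µ in cm⁻¹, and `s` an
acquisition scale (default 1300 counts·mL/(MBq·mm)) chosen so a line
through a ~0.76 MBq/mL vial collects ~10⁴ expected counts — a proxy for a
long acquisition. Scatter, randoms, normalisation, decay and detector
blurring are deliberately omitted: the experiment isolates attenuation.
Observed data are independent Poisson draws, seeded.

Reconstruction is OSEM with the attenuation factors of a *candidate* µ map
inside the system model and its sensitivity (attenuation-weighted
multiplicative updates). Defaults: 21 subsets (angle *i* → subset
*i* mod 21, the standard interleave), 3 iterations, uniform positive
initialisation, zero-sensitivity voxels forced to zero, and a 2 mm FWHM
Gaussian post-filter (σ = FWHM/2.3548 per axis, reflective boundaries,
which conserve the image sum). With one subset the update is classical
MLEM; the tests verify its log-likelihood is non-decreasing over ten
iterations. An all-zero sinogram reconstructs to an all-zero image by
construction (documented, not an error).

## Quantification and the recovery coefficient

A vial measurement is the image mean over a vial-congruent ROI (the same
volume-matched cylinder as the phantom vial) and that mean times the ROI
volume. The recovery coefficient RC = measured/true corrects the
partial-volume spill-out of small objects: `corrected = raw / RC`, exactly
invertible, applied to ROI means only. The whole-volume total counts all
spilled signal and is always reported raw.

The published constant 0.5167 (10 mm diameter) is the default for user
data, but it describes a clinical scanner's point-spread function. The
simulator's PSF is narrower, so `run_experiment` calibrates its own RC by
simulating an isolated 10 mm vial in a uniform soft-tissue cylinder
noiselessly, reconstructing with the true µ map and the same OSEM/filter
settings, and taking the measured/true mean ratio (≈0.905 at the default
settings). This mirrors the original procedure of measuring RCs on a
separate resolution phantom. A `rc_for_diameter` hook accepts a
user-supplied diameter → RC curve.

## Error analysis

Percent error is `100·(measured − baseline)/baseline`, signed. Baselines
are the gold standard (known dispensed activity/concentration) or the
measured reference vial (measured-vs-measured, defined only for the three
joint vials). Error reduction between strategies is `|error_a| − |error_b|`
in percentage points. Inter-observer statistics are signed per-vial
differences (observer 1 − observer 2); the headline "mean difference" is
the magnitude of the *mean signed difference* — that convention, not the
mean of magnitudes, reproduces the published 5.49 % concentration figure
exactly from the printed tables — together with the maximum absolute
difference. Published per-vial error tables ship in
`implantac.reference` as inputs for this exact arithmetic; rounding in the
printed tables means reference-vial errors cannot be regenerated exactly
from them, so only gold-standard arithmetic is treated as exact.

## Experiments

`run_experiment` reconstructs **one** noisy sinogram realisation with every
requested µ-map strategy (as one acquisition was reconstructed with
different maps in the emulated study), measures all vials and the
whole-volume total, and reports per-strategy percent errors plus the
ranking by |whole-volume error|. On the default 128 × 128 × 40 grid the
whole comparison takes seconds and robustly yields
original > simple_tissue > model_accurate with the original error negative
(under-correction), the qualitative surface of the emulated experiment.
Magnitudes are *not* expected to match the cadaver numbers: the desk-scale
geometry, 2-D acquisition and absent scatter/randoms change the scale of
the attenuation deficit.

`misregistration_experiment` displaces the accurate model by 0/2/5/10 mm
along the anterior-posterior axis before inpainting and reports RC-corrected
mean |vial error| per offset and its least-squares slope. Vial errors (not
the signed whole-volume total, which partially cancels between over- and
under-corrected regions) are the trend metric; at default settings they
grow from ≈0.7 % to ≈6.7 % over 10 mm.

## What passing tests do and do not show

The phantom exercises the full method — void inpainting, attenuation-
weighted OSEM, RC quantification, error reporting — under controlled
conditions where the truth is known exactly. It does not model MR physics
(susceptibility, B0, sequence-dependent void shapes), scatter or randoms,
3-D cylindrical scanner geometry, conical vial shapes, or manual-
registration variability beyond parametric rigid offsets. Quantitative
agreement with clinical scanners is therefore out of scope; directional
and arithmetic claims are what the test suite asserts.

## Problem sizes

Simulation experiments run on 128 × 128 × 40 grids (105 views, ~185 radial
bins); oracle comparisons use ≤ 32 × 32 grids; the MLEM monotonicity check
uses a 32 × 32 single-slice disk. These sizes were chosen so the full
comparison, calibration and sensitivity experiments each complete in
seconds while keeping ≥ 25 voxels across a vial diameter footprint.
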