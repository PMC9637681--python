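# implantac

Segmentation-based attenuation correction (AC) and quantification for PET
near metal knee implants, with a digital phantom simulator.

## The problem

PET/MRI could detect inflammatory complications around a total knee
arthroplasty (TKA) early, but the cobalt-chromium femoral and tibial
components attenuate the 511 keV annihilation photons strongly, and the
MR-derived attenuation (µ) map has a signal void around the metal, so it
cannot supply the missing attenuation information. Reconstructing with such
a µ map under-corrects the emission data and biases tracer activity
measurements low by tens of percent.

The remedy implemented here is segmentation-based inpainting of the void:
tissue classes are assigned literature linear attenuation coefficients
(LACs, cm⁻¹ at 511 keV — air 0, soft tissue 0.0927, adipose 0.0854, bone
0.13, polyethylene 0.079, cobalt-chromium 0.72), and rigid placement of
implant component geometry fills the void with the correct metal and
polyethylene coefficients. Four µ-map strategies are compared:

1. **original** — the void keeps the coefficient of air (the uncorrected map);
2. **simple_tissue** — the void is filled uniformly with soft tissue;
3. **model_alternative** — implant models of a different (posterior-stabilised)
   design are placed into the void;
4. **model_accurate** — the implant models matching the phantom's own
   geometry are placed into the void.

## What the package does

Because this is a simulator, no scanner data is needed. The pipeline is:

- **phantom** — a digital knee: soft-tissue/adipose limb, femur/tibia,
  two-metal-component implant with polyethylene insert, and four ~1.5 mL
  tracer vials (reference on the skin, anterior/mid/posterior around the
  joint) with known volumes and activities (totals 6.18 mL, 4.68 MBq,
  ≈0.76 MBq/mL). An MR-style signal void is synthesised by dilating the
  metal by a configurable radius (default 4 mm).
- **mumap** — label→LAC conversion and the four inpainting strategies, with
  rigid model placement (`RigidTransform`, nearest-neighbour resampling).
- **projector / recon** — slice-wise 2-D parallel-beam projection with exact
  Siddon path lengths; attenuation as per-LOR factors `exp(−∫µ dl)`;
  Poisson noise; OSEM reconstruction (default 21 subsets × 3 iterations,
  2 mm Gaussian post-filter) exposed statsmodels-style as
  `EmissionModel(sinogram, mu_map).fit(config) → ReconstructionResult`.
- **quantify** — vial-congruent ROI means and totals with recovery-
  coefficient (RC) partial-volume correction, `corrected = raw / RC`.
  For user data the published constant RC = 0.5167 (10 mm diameter) is the
  default; for simulations the RC is calibrated from a single-vial phantom
  run, because an RC belongs to a specific scanner/reconstruction PSF.
- **errors** — percent errors vs the gold standard and vs the reference
  vial, `100·(measured − baseline)/baseline`; error reductions between
  strategies; inter-observer difference statistics.

## Worked example

```python
import implantac as ia

result = ia.run_experiment(ia.default_run_config(seed=1))
print(result.summary())
```

prints

```
Attenuation-correction strategy comparison
  grid: (128, 128, 40) @ (1.5625, 1.5625, 3.0) mm, seed 1
  calibrated RC: 0.9051
  whole-volume total-activity percent error vs gold standard:
    original             -26.85 %
    simple_tissue        -17.21 %
    model_alternative     +6.34 %
    model_accurate        -0.04 %
  ordering by |error|: original > simple_tissue > model_alternative > model_accurate
```

The uncorrected map under-estimates the total activity by ~27 % (signed
negative error: under-correction), soft-tissue inpainting halves the error,
and placing the accurate implant model essentially removes it — the same
qualitative ranking reported for the cadaver experiment the phantom
emulates. Per-vial RC-corrected means land near the true ≈0.76 MBq/mL:

```python
from implantac.quantify import measurements_frame
print(measurements_frame(result.measurements["model_accurate"]).round(4))
```

```
     vial  volume_ml  mean_raw  mean_rc  total_raw  total_rc     rc
reference     1.5234    0.6787   0.7498     1.0340    1.1423 0.9051
 anterior     1.5308    0.6812   0.7526     1.0428    1.1521 0.9051
      mid     1.5601    0.6780   0.7491     1.0577    1.1686 0.9051
posterior     1.5674    0.6833   0.7550     1.0711    1.1833 0.9051
```

The same pipeline is scriptable from the shell:

```bash
implantac run --out run1 --seed 1 --misregistration
implantac generate-phantom --out phantom/
implantac build-mumap --labels phantom/labels.nii.gz --strategy model \
    --model accurate --out mumap.nii.gz
```

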