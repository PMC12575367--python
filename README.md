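# radialign

Quantification chain for cell-stretching experiments on radially
micropatterned elastic membranes: reconstruction of the planar deformation
field from tracked fiducial beads, θ-sector alignment statistics of cells on
a radial micropattern, and migration-persistence statistics with circular
two-sample tests — plus a synthetic-scene generator with exact ground truth
for validating every estimator.

## Who this is for

Mechanobiology labs running equibiaxial (or any in-plane) stretch
experiments on deformable substrates who need to answer, from fluorescence
time-lapse data:

1. **What deformation did my substrate actually apply?**  Fluorescent beads
   embedded in the membrane are detected (Laplacian-of-Gaussian), linked
   into tracks (two-step nearest-neighbour + gap closing), and turned into a
   deformation-gradient map **F** on a grid by local weighted least squares.
   The right polar decomposition F = R·U separates rotation from pure
   stretch: a well-working equibiaxial stretcher shows rotation ≈ 0°,
   off-diagonal components ≈ 0 and equal principal stretches λ₁ ≈ λ₂, with a
   radial strain gradient profiled over annular bands.
2. **Did my cells align to the pattern?**  The pillar is partitioned into
   10° θ-sectors; each cell's angular alignment γ = orientation − sector
   orientation (axial, wrapped to [-90°, 90°)) is fitted with a Gaussian
   (μ → 0 for aligned populations) and per-sector mean orientations regress
   on sector orientation (slope → 1), overall and stratified by r-band.
3. **Did stimulation change how cells move?**  Nuclei tracks yield rose
   diagrams of step directions, turning-angle distributions, persistence
   (mean resultant length of turning angles), and lognormal speed fits;
   conditions are compared with a permutation two-sample **Kuiper test**
   (V = D⁺ + D⁻, the rotation-invariant circular Kolmogorov–Smirnov
   analogue) under Holm–Bonferroni correction.

`docs/methods.md` documents the models, conventions and numerical choices.

## Worked example

Run the full synthetic demo (field + alignment + migration):

```bash
radialign demo full --seed 7 --out demo_out/
```

`demo_out/summary.json` (abridged; the run is byte-reproducible for a fixed
seed):

```json
{
  "field": {
    "band_strains": [0.038171, 0.078234, 0.122692],
    "ground_truth_mean_strain_bands": [0.025, 0.075, 0.125],
    "mean_rotation_deg": -0.003201,
    "mean_strain_overall": 0.098517
  },
  "alignment": {"mu": 0.02128, "sigma": 8.464371,
                "slope": 0.989464, "r_squared": 0.998605},
  "migration": {
    "flat_undeformed":      {"persistence": 0.214955, "speed_peak": 0.436466},
    "patterned_undeformed": {"persistence": 0.253219, "speed_peak": 0.479694},
    "flat_deformed":        {"persistence": 0.597795, "speed_peak": 0.577827},
    "patterned_deformed":   {"persistence": 0.843188, "speed_peak": 0.661076},
    "significant_pairs": 5
  }
}
```

Reading the numbers: the demo scene applies a radial displacement profile
g(r) = 0.1·r²/R, whose strain grows from centre to rim; the three band
strains recover that gradient (the inner band reads high because the
smoothing neighborhood of the local affine fit averages over the non-smooth
centre; the overall mean strain 0.0985 is within 2 % of the configured 0.1),
and the mean rotation of −0.003° confirms pure stretch.  The 500-cell
population with 8° angular noise gives an alignment fit of μ ≈ 0° and
regression slope ≈ 0.99 — cells follow the pattern.  Migration persistence
orders exactly as the condition presets prescribe (deformed > undeformed,
patterned deformed highest), and 5 of the 6 pairwise Kuiper tests reject
after Holm correction (the two undeformed conditions, which share the same
turning-angle law, do not differ).

Individual stages run on CSV tables with the same schemas real experiments
export (`tracks.csv`: track_id, frame, x_um, y_um; `cells.csv`: cell_id,
x_um, y_um, orientation_deg):

```bash
radialign generate --seed 5 --out scene/
radialign field   --tracks scene/tracks.csv --center 332.8,332.8 --radius 300 --out field_out/
radialign align   --cells scene/cells.csv  --center 332.8,332.8 --out align_out/
radialign migrate --tracks a.csv --condition flat_undeformed \
                  --tracks b.csv --condition patterned_deformed \
                  --nperm 999 --seed 7 --out migrate_out/
radialign validate --seed 0        # property-check suite, non-zero exit on failure
```

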