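# sinusect

Cross-sectional 3D morphometry of sinus cavity masks: landmark-based
reorientation of a head-CT-derived cavity mask, isosurface reconstruction
with anatomical boundary clipping, proportional cross-sectioning with
closed B-spline curve fitting, per-section width / height / aspect-ratio
profiling, and cohort statistics comparing sexes. A synthetic cavity
generator with exact ground truth drives validation end to end.

## Pipeline

1. **orientation** — recover the scan misorientation from two labelled
   landmark lines (cranial base, nasal septum) and realign the volume or
   mesh. Rotations are named by the anatomical view in which they are
   observed (sagittal / axial / coronal), composed coronal → axial →
   sagittal.
2. **reconstruct** — marching-cubes isosurface of the binary mask
   (anti-aliased, largest component), then clipping by the superior /
   lateral / medial boundary surfaces (planes or heightfields). The
   inferior side is never clipped; the cavity's own lower envelope is the
   inferior limit.
3. **morphometry** — cavity length `L` is the anteroposterior extent;
   cutting planes at every 10% of `L` intersect the mesh, the pooled
   cutting points are fitted with a periodic cubic B-spline, and each
   section reports width `W` (mediolateral extent), height `H`
   (superoinferior extent) and aspect ratio `AR = W/H`.
4. **stats** — KS normality screening, pooled-variance t-tests between
   sexes per parameter, anterior (10–50%) vs posterior (50–90%)
   aspect-ratio contrasts, left–right symmetry, and exact noncentral-t
   post-hoc power.
5. **synthetic** — superellipse-tube cavities with configurable
   width/height profiles, a sex width multiplier, random rigid
   misorientation, bounded surface noise, optional internal septa, and a
   stored analytic ground truth.

## CLI

```sh
sinusect generate --config spec.yaml --out data/ --seed 7
sinusect reorient --mask data/f000_left.nii.gz \
    --landmarks data/f000_left.landmarks.json \
    --out aligned.nii.gz --report angles.json
sinusect reconstruct --mask aligned.nii.gz --boundary boundary.json --out es.ply
sinusect measure --mesh es.ply --meta meta.json --out profile.csv
sinusect cohort-stats --profiles profiles.csv --out report.json --table table1.csv
sinusect run --input-dir data/ --output-dir out/      # end to end
```

`generate` writes NIfTI masks, landmark JSONs, `ground_truth.csv` and
`meta.csv`; `run` consumes the same layout and produces `profiles.csv`
(one row per subject/side/fraction), `report.json` and `provenance.json`.

## Conventions

All geometry is in millimetres with axes +X mediolateral, +Y
anteroposterior, +Z superoinferior; angles are degrees at every
interface. Masks are NIfTI (spacing/origin in the affine), meshes PLY
(ascii) or STL (binary write), landmarks and boundaries JSON, profiles
and tables CSV, configuration YAML.
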