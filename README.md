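# patchquant

Quantitative fluorescence microscopy of endocytic actin patches in fission
yeast: count GFP-tagged molecules over time in single patches and measure
how fast the branched actin network assembles.

Endocytosis in *S. pombe* builds a transient (~20 s) patch of branched
actin at each internalization site.  With a GFP-tagged patch marker such as
fimbrin imaged as short confocal time-lapse movies (six Z-sections, 1-s
intervals, 60 s), the patch's integrated fluorescence tracks its molecule
content — provided the raw intensities are corrected for camera offset,
uneven illumination and photobleaching, and converted to molecules with a
calibration built from strains whose per-cell copy numbers are known from
quantitative immunoblotting.  `patchquant` implements that entire chain as
a tested library plus CLI:

1. **corrections** — dark-frame/flat-field correction; 2-D Gaussian fit to
   the illumination reference; automatic cropping of poorly illuminated
   areas (largest adequately lit rectangle).
2. **photobleach** — two-Gaussian fit to the pixel-brightness histogram,
   threshold at 95 % predicted intracellular purity, 8-of-10-frame voting
   mask, double-exponential fit
   `I(t) = A (a₁ e^{−k₁ t} + a₂ e^{−k₂ t})` to the median intracellular
   brightness, division by the normalized decay.
3. **calibration** — segment cells on Z-sum projections, measure
   background-corrected totals, subtract autofluorescence (nonfluorescent
   control strain), regress per-strain mean intensity on known molecules:
   the slope converts any integrated intensity to molecules.
4. **tracking** — Laplacian-of-Gaussian spot detection on
   temporal-median-subtracted projections, greedy nearest-neighbour
   linking, automated screening (events missing the start of assembly or
   the end of disassembly, or overlapping another patch, are rejected).
5. **alignment** — temporal super-resolution realignment: continuous
   per-track time offsets fitted iteratively against the running mean, so
   hundreds of events average into a smooth mean ± SD molecules-vs-time
   curve on a 0.1-s grid.
6. **kinetics** — straight-line fits to the most linear 3.7-s windows of
   the assembly and disassembly phases (minimum RMS residual over all
   window placements); replicate means per strain; liquid-culture growth
   rates from the slope of log₂(OD) over the first eight time points.
7. **synth** — a synthetic-movie generator (cells, patches with triangular
   molecule-count profiles, bleaching, Poisson-Gaussian camera noise) whose
   exact ground truth backs every test in the suite.

The assembly rate reported for a strain is the slope (molecules/s) of the
most linear 3.7-s window of the rising phase of its aligned mean curve,
averaged over 3–4 replicate movies.

## Worked example

Render a synthetic movie with known truth (20 patches assembling at
50 molecules/s to a 500-molecule peak, bleaching with
a₁ = 0.3, k₁ = 0.1 s⁻¹, a₂ = 0.7, k₂ = 0.005 s⁻¹) and run the full
pipeline:

```python
import numpy as np
import patchquant as pq

spec = pq.SceneSpec(image_shape=(320, 320), rng_seed=1)
rng = np.random.default_rng(1)
cells = pq.synth.place_cells(spec, 20, rng)
patches = pq.synth.place_patches(spec, cells, 20, rng)   # 50 molecules/s
stack, truth = pq.render_patch_movie(
    spec, cells, patches, pq.BleachModel(a1=0.3, k1=0.1, a2=0.7, k2=0.005))
dark, flat = pq.make_reference_images(spec)

cal = pq.CalibrationCurve(slope=truth.calibration_slope, intercept=0.0,
                          r_squared=1.0)
result = pq.process_movie(stack, dark, flat, calibration=cal)

b = result.bleach_report["bleach"]
print(f"accepted tracks:  {len(result.tracks)}")
print(f"bleach fit:       k1 = {b['k1']:.3f}/s, k2 = {b['k2']:.4f}/s")
print(f"mean-curve peak:  {np.nanmax(result.curve.mean):.0f} molecules")
print(f"assembly rate:    {result.assembly.slope:.1f} molecules/s")
print(f"disassembly rate: {result.disassembly.slope:.1f} molecules/s")
```

```
accepted tracks:  20
bleach fit:       k1 = 0.112/s, k2 = 0.0057/s
mean-curve peak:  472 molecules
assembly rate:    47.9 molecules/s
disassembly rate: -39.7 molecules/s
```

All 20 events pass screening; the fitted decay constants sit within ~12 %
of the generator's, the aligned peak within ~6 % of the true 500 molecules
(1-s sampling flattens the triangle tip slightly — see
`docs/methods.md`), and the assembly-rate estimate within ~4 % of the true
50 molecules/s.  The disassembly slope is negative by convention.

The same chain is available from the shell, stage by stage:

```sh
patchquant simulate scene.json movie_dir/
patchquant correct movie_dir/stack.tiff --dark movie_dir/dark.tiff \
    --flat movie_dir/flat.tiff -o corrected/
patchquant calibrate manifest.csv --dark dark.tiff --flat flat.tiff -o curve.json
patchquant track corrected/corrected.tiff -o tracks.csv
patchquant align tracks.csv --calibration curve.json -o curve.csv
patchquant rate curve.csv -o rates.csv --strain wt
```

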