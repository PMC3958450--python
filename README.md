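# odyn — organelle dynamics from time-lapse fluorescence microscopy

`odyn` quantifies three live-cell imaging readouts that together characterize
organelle health in cultured cells (originally: wild-type versus
ceramide-transfer-deficient mouse embryonic fibroblasts):

1. **Mitochondrial morphology dynamics.** Mitochondria in healthy fibroblasts
   form long tubules (5–10 µm) that continuously remodel; stressed cells show
   short fragments (1–3 µm) that barely change. `odyn` segments each frame
   into single-pixel-wide centerlines — an adaptive local *MidGrey* threshold
   (pixel is foreground iff `I > (local_min + local_max)/2`, disk radius 15 px)
   followed by a medial-axis transform for fragmented morphologies, or
   Hessian-ridge (tubeness) tracing for tubular networks — links objects
   across frames by Hungarian assignment of centerline centroids with gap
   closing (Crocker–Grier-style), and reports per-track statistics. The
   headline statistic is the **dynamic range** of the length series
   `L(t)`:

   `DR = 100 · (max L − min L) / mean L  [%]`

   together with net displacement, path length, and the confinement ratio
   (net/path) as a directionality measure.

2. **FRAP mobile fractions.** Recovery of fluorescence into a bleached
   region follows `F(t) = F0 + (F∞ − F0)(1 − e^(−t/τ))`; the mobile fraction
   is `(F∞ − F0)/(F_pre − F0)`. `odyn` locates the bleach, evaluates the
   percent recovery at any time (linear interpolation between 2-min samples),
   and fits `F∞, τ` by least squares with `F0` fixed at the measured
   post-bleach floor.

3. **Autophagy puncta scoring.** Bright LC3-like spots are detected by
   multi-scale Laplacian-of-Gaussian filtering with a robust brightness gate
   (peak > background median + k·MAD), counted per cell against a provided
   label image; a cell with **more than 5** puncta is scored positive, and
   the *autophagy index* of a condition is the mean count per cell.

Because the raw microscopy of the original study is not publicly deposited,
the package ships a first-class synthetic-data generator
(`odyn.synthetic_data`) whose presets encode the published conditions
(0.09 µm/pixel, 109 s/frame, 8-bit; control tubules with dynamic range 1.0,
mutant fragments with 0.15; FRAP presets recovering ~90% / ~50% at 15 min)
and records exact ground truth, so the entire chain is testable end to end.

## Worked example

Run the mitochondrial pipeline on a simulated fragmented-morphology movie
(8 frames, 512×512, seeded):

```python
from odyn import pipeline

cfg = {"input": {"preset": "mutant_mito", "n_frames": 8},
       "segmentation": {"mode": "midgrey"}}
res = pipeline.run_mito(cfg, seed=2)
s = res["summary"]
print(len(res["tracks"]), "tracks")
print("median length        ", round(s.condition["mean_length_um"]["median"], 3), "um")
print("median dynamic range ", round(s.condition["dynamic_range_pct"]["median"], 1), "%")
```

prints

```
14 tracks
median length         2.161 um
median dynamic range  16.3 %
```

i.e. fourteen fragments of ~2.2 µm whose lengths vary by ~16% over the
16-minute observation — the fragmented, remodeling-arrested phenotype (a
control-preset movie in `ridge` mode yields ~7.5 µm tubules at ~101%).
A FRAP curve is analysed in three calls:

```python
from odyn import frap, synthetic_data

curve, _ = synthetic_data.generate_frap_series_from_preset("mutant_frap", seed=3)
curve.bleach_index = frap.detect_bleach(curve)
fit = frap.fit_recovery(curve)
print(round(fit.mobile_fraction, 3), round(fit.tau_s), round(frap.recovery_percent(curve, 900), 1))
# -> 0.552 365 50.4
```

The same stages are scriptable from the shell:

```sh
odyn synth mito --preset mutant_mito --frames 8 --seed 2 --out data/
odyn mito  --config run.yaml --seed 2 --out results/
odyn frap  --config frap.yaml --out results/
odyn puncta --config puncta.yaml --seed 7 --out results/
```

All stage parameters (segmentation mode and thresholds, tracking
displacement cap and memory, FRAP evaluation time, puncta detection scales)
live in the YAML config; outputs are CSV tables and JSON summaries.

## Layout

| module | role |
|---|---|
| `odyn.imaging_io` | calibrated TIFF stacks, ROIs, focus selection, YAML config |
| `odyn.synthetic_data` | movie / FRAP / puncta generators with ground truth |
| `odyn.segmentation` | MidGrey + medial axis, ridge tracing, length measurement |
| `odyn.tracking` | centroid linking with gap closing |
| `odyn.dynamics` | per-track dynamic range, displacement, directionality |
| `odyn.frap` | bleach detection, recovery curves, mobile-fraction fits |
| `odyn.puncta` | spot detection, per-cell counts, autophagy index |
| `odyn.pipeline` / `odyn.cli` | orchestration and the `odyn` command |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
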