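# octlumen

Automatic lumen segmentation for intravascular optical coherence tomography
(IVOCT) pullbacks.

IVOCT images coronary arteries from inside the vessel at 10–20 µm resolution;
the lumen contour per frame and the lumen-area curve along the pullback are
what cardiologists use to grade a stenosis and size stents. Manual tracing
takes hours per pullback, and automatic methods must cope with three
recurring difficulties: irregular, non-circular lumens (plaque,
bifurcations), the dark radial shadow cast by the guide wire, and residual
blood speckle inside the lumen.

`octlumen` implements a level-set pipeline built around three ideas:

1. **Distance-regularized level set (DRLS).** On the polar-unwrapped frame,
   the contour is the zero level set of a field ϕ evolved by

       ∂ϕ/∂t = μ div(d(|∇ϕ|)∇ϕ) + λ δ(ϕ) div(g ∇ϕ/|∇ϕ|) + α g δ(ϕ),

   where g = 1/(1+|∇I|²) is the edge indicator. The double-well regularizer
   keeps |∇ϕ| ≈ 1 near the contour (no reinitialization), the α (area) term
   expands the front from an initialization line just outside the catheter,
   and g stalls the flow on the bright wall edge. Defaults: μ = 0.2, λ = 5,
   α = 9 for the first 100 iterations then 2.
2. **Divide-and-conquer guide-wire handling.** The shadow sector is detected
   once per pullback on the *stripe map* (per-frame normalized column sums,
   stacked; the shadow is a dark continuous river) via Otsu thresholding and
   morphology, the occluded columns are removed before evolution, and the
   boundary across the gap is reconstructed afterwards by a 9th-order
   polynomial fitted through 10 boundary points flanking each side.
3. **Narrow N×1 smoothing.** A 1-D Gaussian (N = 20, σ = 4) applied along
   each A-line flattens thin blood artifacts without mixing columns, so
   boundary jumps between adjacent A-lines — bifurcations, cut edges —
   survive; an N×N kernel at the same σ blurs them and causes leakage.

Evaluation uses the Dice similarity coefficient in percent,
DSC = 2|S_a∩S_m|/(|S_a|+|S_m|)×100, computed on Cartesian rasterizations,
plus the lumen-area curve and MLA (minimal luminal area) localization.

Clinical pullbacks are not redistributable, so the package ships a phantom
generator (`octlumen.phantom`) producing polar pullbacks with exact ground
truth for each challenge — irregular/bifurcated boundaries, a drifting wire
shadow, artifact blobs, speckle, stenosis — individually switchable. See
`docs/methods.md` for the model, parameter rationale, and what the phantoms
do and do not emulate.

## Worked example

```python
import numpy as np
from octlumen import phantom, pipeline, metrics

# a 4-frame pullback with all three challenges switched on
spec = phantom.full_combined(seed=5, n_frames=4)
frames, truth = phantom.generate_pullback(spec)

results = pipeline.segment_pullback(frames, pipeline.PipelineConfig())
table, mean, sd = pipeline.evaluate(results, truth.radii)
print(f"mean DSC {mean:.2f}% +- {sd:.2f}%")
for r in results:
    err = np.abs(r.contour.radius_by_column - truth.radii[r.frame_index])
    print(f"frame {r.frame_index}: {r.iterations} iterations, "
          f"gap {r.gap_width} cols, boundary err {err.mean():.2f} rows")
```

prints (exactly, given the fixed seed):

```
mean DSC 99.53% +- 0.29%
frame 0: 1820 iterations, gap 24 cols, boundary err 0.52 rows
frame 1: 1810 iterations, gap 24 cols, boundary err 0.52 rows
frame 2: 1800 iterations, gap 24 cols, boundary err 0.55 rows
frame 3: 1710 iterations, gap 24 cols, boundary err 1.97 rows
```

Mean DSC 99.53% says the segmented lumen and the ground truth overlap almost
perfectly in area; the per-frame boundary error of ~0.5 rows is ~5 µm at the
default 10 µm/pixel scale. The 24-column gap is the detected wire shadow
(20 true columns plus the dilation safety margin), reconstructed by the
polynomial fit.

The same workflow from the shell:

```
oct-phantom --scenario full --frames 4 --out ph/
oct-lumen segment --input ph/pullback.tif --space polar --out seg/
oct-lumen evaluate --pred seg/contours.csv --truth ph/truth.csv
```

`segment` writes per-column contours (CSV, with polar and Cartesian
coordinates and a level-set/fitted provenance flag), a Cartesian mask stack
(TIFF), the guide-wire track (CSV) and a config echo (JSON).

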