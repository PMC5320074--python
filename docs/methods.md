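# Methods

`octlumen` segments the arterial lumen in intravascular OCT (IVOCT) pullbacks.
A pullback is an ordered sequence of cross-sectional frames acquired while the
imaging catheter is withdrawn through a coronary artery; each frame is a set
of radial intensity profiles (A-lines) around the catheter axis. Clinically,
the quantity of interest is the lumen contour per frame and the derived lumen
area curve, whose minimum (the minimal luminal area, MLA) grades stenosis
severity.

## The segmentation model

All processing happens on the polar-unwrapped frame (rows = radial depth,
columns = A-lines over [0, 2π)), where the lumen boundary is a roughly
horizontal curve r(θ). The contour is the zero level set of a scalar field
ϕ(x) evolved by distance-regularized level-set (DRLS) gradient flow:

    ∂ϕ/∂t = μ div(d(|∇ϕ|) ∇ϕ) + λ δ_ε(ϕ) div(g ∇ϕ/|∇ϕ|) + α g δ_ε(ϕ)

with the edge indicator g = 1/(1 + |∇I|²) of the smoothed image I, the
compact cosine Dirac δ_ε, and the double-well diffusion rate
d(s) = p′(s)/s, where p has minima at s = 0 and s = 1. The well at s = 1
maintains |∇ϕ| ≈ 1 near the contour (no reinitialization needed); the well
at s = 0 permits flat far fields. ϕ is positive on the inner (small-radius)
side; the initialization is a binary step (±2) across a horizontal line a few
rows outside the catheter, and the area term expands the positive region
until the front meets the bright vessel-wall edge, where g → 0 and the flow
stalls. A region-based (piecewise-constant) energy would be a poor fit here:
guide-wire shadows and blood artifacts make the lumen interior strongly
inhomogeneous, whereas the wall edge itself is a reliable gradient feature.

Discretization: explicit Euler with central differences, replicate (Neumann)
borders on all four sides, and the regularization term split as
div((d−1)∇ϕ) + ∇²ϕ with a 5-point Laplacian to avoid the odd-even
decoupling of a doubly central-differenced divergence. `|∇ϕ|` is floored at
1e−10 inside the normalized-gradient term. The same discretization is
implemented twice — a vectorized numpy path and a fused numba kernel — and
their equality is asserted in the tests; one evolution step on a
384×340-pixel frame costs about 4 ms in the jitted path.

Columns are *not* treated periodically during evolution: the working frame
has had the guide-wire sector removed and re-glued, so its left/right edges
are a genuine cut, and the original angular seam lies inside the merged
frame.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| μ | 0.2 | — | distance-regularizer weight; stability needs μ·dt < 1/4 |
| λ | 5 | — | edge-weighted length (curvature) term |
| α | 9 for 100 iterations, then 2 | — | expansion speed; large early to escape the catheter region, small later to avoid leakage |
| dt | 1.0 | — | time step |
| ε | 1.5 | rows | Dirac/Heaviside half-width |
| max_iters | 3000 | — | iteration cap (see below) |
| conv_tol | 1e−3 | — | early stop on mean |Δϕ| near the interface |
| edge_scale | 255 | — | intensity scale for the edge indicator |
| K, M | 10, 9 | — | gap fit: support points per side, polynomial order |
| N, σ | 20, 4 | rows | narrow smoothing kernel (21 taps; even N widened to N+1 for symmetry) |

Two of these deserve justification:

**edge_scale.** The classic DRLS parameter values above were established on
8-bit images, where wall-edge gradients reach tens of grey levels and
g = 1/(1+|∇I|²) drops to ~10⁻³ at the boundary. This package normalizes
images to [0, 1] floats for all other processing, on which |∇I| ≲ 0.1 and g
would stay ≈ 1 everywhere — the front would never stop. The edge indicator is
therefore computed on the image times `edge_scale` (default 255, i.e. the
8-bit convention).

**max_iters.** The front advances at ~0.2–0.4 rows/iteration (the pace is
limited by how fast the regularizer rebuilds the profile's feet, not by α),
and decelerates asymptotically inside the low-g approach zone of the edge.
Crossing a realistic lumen radius (~115–165 rows from the initialization
line) plus settling into the g-valley takes ~1500–2600 iterations, so the cap
is 3000 with an early stop when the interface essentially stops moving
(mean |Δϕ| over the near-interface band < conv_tol, checked every 10
iterations once the final α stage is active). Convergence is therefore
governed by the stopping rule, not the cap; doubling `max_iters` does not
move the result.

**The signed-distance diagnostic.** `mean_grad_near_zero` reports
mean |∇ϕ| over pixels straddling the zero crossing (within the |ϕ| ≤ ε
value band). A value-band-only statistic would be dominated by the region
the front has swept, which saturates at ϕ → ε⁻ where the Dirac support — and
hence the area term — ends; that plateau is flat (s = 0 is the double-well's
other minimum, deliberately), sits far from the contour, and says nothing
about the interface. At the interface itself the converged profile has slope
≈ 0.9–1.1.

## Guide-wire divide-and-conquer

The wire's shadow is found pullback-wide on the *stripe map*: per frame, sum
each column's intensities and min–max normalize (a constant frame maps to
0.5); stack frames as rows. The shadow forms a dark continuous "river"
(the wire drifts only slowly frame to frame), segmented by Otsu's threshold
on the 256-bin histogram, then morphological closing (disk radius 2),
removal of components with area < 30 map-pixels, and dilation (disk radius 2,
the safety margin absorbing the wire's bright-reflection columns).
Morphology runs on a 3× column tiling so the periodic seam is invisible to
it. Per frame the interval is the widest periodic run of mask columns (ties
to the darkest run); frames without a detection inherit the nearest detected
frame's interval. Because Otsu always bisects a histogram, a detected run
wider than 25% of the angular range is treated as a non-detection — in a
wire-free pullback the "dark class" is just the darker half of the natural
per-column variation, not a shadow.

Removal deletes the interval's columns and concatenates the rest starting
just after the interval, recording a column map. After segmentation, the
boundary radii of K = 10 columns flanking each side of the gap are fitted
with an M = 9 least-squares polynomial on the unwrapped column index
(numpy's `Polynomial.fit`, whose domain mapping keeps the ninth-order
Vandermonde well conditioned), evaluated across the gap, and clamped to the
frame. With 2K = 20 support points the fit is near-interpolatory and can
oscillate on rough flanks; an optional cubic fallback triggers when the
fitted gap's total variation exceeds 3× the flanking boundary's (off by
default, matching the reference procedure).

## Narrow smoothing

Blood artifacts and the catheter sheath are thin structures lying mostly
perpendicular to the A-scan direction, while genuine boundary jumps
(bifurcation openings, the guide-wire cut) occur *between* neighbouring
A-lines. A 1-D Gaussian (nominally N = 20 taps, σ = 4 rows, applied along
each column independently with mirror borders) therefore flattens artifacts
enough for the front to pass, while leaving cross-column discontinuities
perfectly sharp — an N×N kernel at the same σ blurs those jumps and lets the
level set leak through weak boundaries. The N×N filter is included only for
the comparison experiment.

## Phantoms: what they emulate and what they don't

The clinical pullbacks the method was designed for are not redistributable,
so the package ships a parametric phantom generator producing polar pullbacks
with exact ground truth: a bright wall band entered at r(θ) (ground truth =
ramp midpoint) over a dark lumen, a catheter sheath ring, a wire reflection
*inside* the lumen (default radius 60 rows) whose shadow attenuates
everything beyond it — including the wall — drifting smoothly along the
pullback, thin bright artifact blobs in the lumen, multiplicative Gaussian
speckle, an optional harmonic-irregular boundary, a raised-cosine notch as a
bifurcation surrogate, and an optional smooth stenosis in the frame
direction. Default geometry: 384 radii × 360 A-lines at 10 µm/pixel, lumen
radius 150 rows (1.5 mm) — these are the problem sizes used by the test
suite and the acceptance script throughout.

Randomness is seeded per (spec seed, frame index), so pullbacks are
byte-reproducible and frames independent of generation order.

Deliberately not modelled: realistic OCT speckle statistics (the noise is
i.i.d. multiplicative Gaussian), depth-dependent attenuation, catheter
eccentricity distortion, stent struts, or wire shadows wider than one sector.
Passing on phantoms therefore demonstrates the mechanics of the pipeline —
coordinate handling, detection, removal/fitting, evolution, metrics — under
controlled difficulty, not clinical-grade accuracy on real tissue texture.

In the combined-challenge scenario the bifurcation notch is placed opposite
the wire track. This is not a simplification of the segmentation task but an
honest statement of a method limitation: the gap fit can only interpolate
smooth structure across the shadow, so a side branch hidden entirely behind
the wire is unrecoverable by construction.

## Evaluation

Dice similarity is computed in percent, DSC = 2|S_a ∩ S_m|/(|S_a| + |S_m|) ×
100, on *Cartesian* rasterizations of both contours (the same polygon-fill
routine for prediction and reference): on the polar grid a pixel near the
catheter subtends far less physical area than one at large radius, so
polar-grid Dice would over-weight the catheter region. Two empty masks are
defined to agree perfectly (DSC 100, logged as degenerate). Lumen area is
the Cartesian true-pixel count times the pixel area (spacing², mm²); the
area curve's argmin/argmax (ties to the lowest frame index) give the MLA and
maximal-area frames.

## Degenerate inputs and edge cases

* Constant frames: stripe normalization is 0/0 — the stripe is defined as
  0.5 and logged.
* Columns where ϕ never crosses zero are interpolated from their periodic
  neighbours; more than 20% missing raises a segmentation failure for that
  frame. The pipeline records per-frame failures and continues.
* Non-finite ϕ during evolution raises a numerical-instability error naming
  the iteration (the practical cause is an oversized time step).
* Gap fitting reduces K when flanking columns are missing, as long as the
  fit stays overdetermined (2K ≥ M + 1).
* The α-term sign is fixed so that the *configured positive* α values expand
  the inner-positive field; with the opposite textbook sign convention the
  same magnitudes would be written as negative.

## Known limitations

* Single guide wire only; no stent-strut shadows.
* The boundary position inherits a small inward bias (~0.2–0.5 rows on
  phantoms) because the front approaches the g-valley asymptotically from
  inside; at 10 µm/row this is well below clinical relevance.
* Evolution cost is ~5–10 s per frame at the default iteration budget on one
  CPU core; the narrow-band or multigrid accelerations of the level-set
  literature are out of scope.
* The polar unwrap assumes the catheter axis is the image center (no
  eccentricity correction), and the inverse transform zero-fills outside the
  sampled annulus.
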