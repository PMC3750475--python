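# Methods

This note documents the models, parameters and numerical choices behind
zebreg, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Coordinate and intensity conventions

All coordinates are `(row, col)` with the origin at the top-left and rows
increasing downward; every module uses this convention and the test suite
checks it with asymmetric (3×5) fixtures. Intensities stay on their native
scale — an 8-bit image is processed with values 0..255, a 16-bit one with
0..65535. Every stage is either scale-covariant (Otsu with relative
binning, MAD-based thresholds, least-squares β) or works on differences,
so no [0, 1] normalization is needed, and none is applied.

## Outline segmentation

The body mask is `largest_component(close(otsu ∨ edges, disk(25)))`, holes
filled, where

* **Otsu** maximizes between-class variance on a 256-bin histogram
  spanning `[min, max]` (equal-width bins regardless of bit depth — a
  deterministic choice that makes the threshold reproducible across input
  types). The threshold is the center of the last background bin and the
  mask is `intensity > threshold`. A constant image has no threshold and
  raises a degenerate-input error.
* **Edges** are zero crossings of a 13×13, σ = 2 Laplacian-of-Gaussian
  response (kernel re-centered to exactly zero mean, reflective borders).
  A crossing counts only when (a) the response difference across the
  4-neighbor pair exceeds `max(10⁻³·dynamic range, 6·σ̂_d)`, where `σ̂_d`
  is the MAD-based robust sigma of all neighbor response differences —
  without the noise-adaptive term, sensor noise marks essentially the
  whole background as edges and the subsequent closing floods the canvas;
  and (b) both responses are at least `10⁻⁴` of the response maximum in
  magnitude — the truncated kernel support otherwise produces a spurious
  ring of "crossings" ~6 px outside every strong edge where the response
  jumps from its last side-lobe value to ≈ 0. Only the negative-response
  (locally brighter) pixel of each crossing pair is marked, so edge bands
  hug the bright structure instead of dilating it.
* Edge components smaller than 10 px are discarded before the OR: real
  edges (outline, vasculature) are long curves, while isolated noise
  crossings sitting a few pixels off the body would be welded on by the
  radius-25 closing and inflate the body by several percent.
* **Closing** by a Euclidean disk is computed with two exact distance
  transforms (dilation = `dt(¬A) ≤ r`, erosion = `dt(A) > r`). This is the
  algebraic closing by the discrete disk `{d : |d| ≤ r}` — extensive and
  idempotent, both property-tested — and is much faster than a 51×51
  footprint filter.
* **Boundary tracing** is Moore-neighbor following with Jacob's stopping
  criterion, clockwise from the topmost-then-leftmost boundary pixel. The
  start/orientation rule is a canonical form so landmark indexing is
  bit-reproducible. Hole filling before tracing guarantees the contour is
  the outer boundary; interior holes (e.g. a dark yolk in DIC) never leak
  into it.

DIC images are handled by negating intensities (`invert=True`); nothing
else changes.

## Landmarks

Head and tail are the exact maximum-distance contour pair (brute force
over all pairs; ties broken toward the lexicographically smallest pair).
The head is the endpoint whose perpendicular contour extent over the
nearest 10% of the major axis is larger — at 2–5 dpf the head/yolk end is
clearly wider than the tail.

Automatic landmarks (default 17) are the two endpoints plus interior
points at equal arc-length spacing. Two contour arcs are excluded: a
fraction 0.15 of total arc length centered on the tail endpoint and 0.10
centered on the ventral (yolk) anchor, because those regions vary too much
between individuals to define correspondences. The ventral anchor is the
*median arc position* of all contour points within 2 px of the maximum
row: the discretized bottom of the yolk bulge is flat, so the single
argmax pixel jitters by tens of pixels between individuals and would
desynchronize every downstream landmark. Interior landmarks are allocated
to the two head–tail sides proportionally to admissible arc length
(with a ±1 adjustment that balances the per-side spacing) and spaced
equally within each side, so spacing stays anchored at both endpoints and
equal landmark indices on two fish correspond to roughly equal arc
fractions. Correspondence is then simply by index; manual pairs append
with the same unit weight.

## Thin-plate-spline registration

The transformation is `f(x) = affine(x) + Σ wᵢ U(‖x − pᵢ‖)` with
`U(r) = r² log r` (the 2D biharmonic Green's function, `U(0) = 0`), fitted
per output coordinate by solving the bordered system

```
[ K + λ·diag(σᵢ²)   P ] [w]   [q]
[ Pᵀ                0 ] [a] = [0]
```

with `K_ij = U(‖pᵢ − pⱼ‖)` and `P` rows `(1, rowᵢ, colᵢ)`. The side
conditions `Σwᵢ = 0`, `Σwᵢpᵢ = 0` keep the bending energy finite; on that
subspace the problem is convex, so the solution globally minimizes
`J = Σ‖qᵢ − f(pᵢ)‖²/σᵢ² + λ·wᵀKw` (verified by a 2000-candidate
perturbation test). Numerical notes:

* `λ = 0` is solved as `λ = 10⁻¹⁰` so interpolation and smoothing share
  one code path; the reported objective uses the requested λ.
* The bending energy is reported as the quadratic form `wᵀKw` (summed over
  output coordinates), which is what λ multiplies in the solve. The
  physical integral `∬ f_xx² + 2f_xy² + f_yy² dx dy` equals `8π·wᵀKw`; a
  property test confirms this by numerical integration over a 10× bounding
  box to 2% (a 3× box truncates the slowly decaying tail by ~3%).
* Collinear or duplicated source landmarks make the system singular and
  raise a dedicated error (checked via the rank of `P` and the solve).
* Default λ = 300 with σᵢ = 1. On landmark coordinates of order 10²–10³
  the kernel entries are of order 10⁵–10⁶, so λ = 300 is a mild smoothing:
  residuals stay well below a pixel while the warp stays smooth between
  landmarks.

Both directions are fitted from one landmark set. Image resampling onto
the reference grid uses the reference→target fit as a backward map
(bilinear, out-of-bounds 0); atlas masks are pulled onto the target grid
with the target→reference fit (nearest-neighbor). Backward mapping avoids
holes; no forward splatting exists in the package. Coordinates within
10⁻⁶ px of the image extent are snapped onto it before sampling, because
the interpolator treats a coordinate of −10⁻¹⁵ as fully out of bounds and
an identity transform would otherwise zero the first row and column.

## Spot detection

The à-trous decomposition smooths with the separable B3-spline kernel
`[1/16, 1/4, 3/8, 1/4, 1/16]`, dilated at level `i` by inserting
`2^{i−1} − 1` zeros between taps (rows first, then columns, reflective
borders). The detail is `W_i = A_{i−1} − A_i`, under which bright spots
give positive coefficients and `A_J + ΣW_i = A_0` holds to round-off; note
the opposite sign convention (`A_i − A_{i−1}`) appears in parts of the
literature, but with it, bright-spot products at odd `J` would be negative
and product thresholding would fail, so this package uses the
positive-spot convention throughout.

Defaults: `J = 3` levels (sensitive to spot radii of roughly 1–8 px,
matching labeled cells at typical stereomicroscope magnifications),
per-level hard threshold `k = 3` robust sigmas (`σ̂ = MAD/0.6745` of each
detail plane), product support `P_J > 0`, minimum component area 4 px,
8-connected labeling. Detected spot counts are monotonically
non-increasing in `k` (property-tested).

Bleed-through correction models the measured red channel as `I = R + βG`
with `R` sparse and estimates `β̂ = ⟨I,G⟩/⟨G,G⟩` — least squares with no
intercept, as the model has none; any constant background should be
removed upstream. The corrected channel is clamped at zero. The stage is
optional and off by default (`--bleedthrough` enables it): it is a
property of a particular camera/filter combination, not of the method.

## Quantification

* Simpson coefficient `|A∩B|/min(|A|,|B|)`: 1 when the smaller mask is a
  subset of the larger, 0 when disjoint, undefined (error) when both masks
  are empty. When exactly one mask is empty — e.g. a small organ mapped
  out of frame — the coefficient is reported as 0: the registered mask
  overlaps nothing. Organs with both masks empty are listed as missing and
  excluded from the unweighted mean.
* Coverage = `|spots ∩ organ| / |organ|` per organ; organs may overlap and
  a spot pixel then counts once per organ (the alternative — splitting
  pixels between overlapping organs — would make a single organ's fraction
  depend on unrelated masks). Empty organs yield a flagged missing value,
  excluded from aggregation means and group sizes.
* Subdivision cuts a mask into equal-width column bands over its column
  extent, ordered head→tail. This assumes horizontal alignment (head
  left); a curved body-axis parameterization is out of scope.

## The phantom generator

`PhantomSpec` defaults define the synthetic study conditions:

| parameter | default | meaning |
|---|---|---|
| canvas | 600×1200 px | frame size; body ≈ 1000 px long |
| body_intensity / texture_amplitude | 120 / 30 | body brightness and vasculature-like ridge pattern |
| noise_sigma | 3 | additive Gaussian noise (body SNR ≈ 40) |
| deform_scale | 10 px | control-point displacement of the inter-individual deformation (~1% of body length) |
| n_spots / n_yolk_spots | 10 / 6 | injected spots; most in the yolk, where cells are injected |
| spot_amplitude / spot_sigma | 150 / 2 px | Gaussian spot profiles, 50 noise sigmas |
| beta | 0.25 | green→red bleed-through coefficient |

The body is a head/trunk ellipse plus a tapering tail and a ventral yolk
bulge, with the part-junction notches smoothed (Gaussian blur of the
indicator, re-thresholded) because real embryo silhouettes have no sharp
concave corners. Seven organs replicate the standard atlas regions, with
the otic vesicle (~320 px) and pectoral fin (~490 px) deliberately small —
small organs are where automatic contour landmarks are expected to
struggle. Deformations are seeded TPS displacement fields (8 jittered
control points + 4 fixed corner anchors) applied as backward maps, checked
for a positive Jacobian on a grid; a folding field raises an error rather
than producing silently invalid ground truth. Spot centers are drawn with
a minimum separation (relaxed deterministically if a region is too small)
so detection matching is unambiguous. All randomness passes through
per-purpose child streams of the spec seed, so identical seeds give
bit-identical phantoms.

Because ground-truth deformations come from the same TPS family the
registration fits, the end-to-end experiment is a parameter-recovery test,
not a model-mismatch test; a `deform` field built from non-TPS local bumps
would probe robustness instead, and phantom results generally bound real
performance from above. The phantom also does not emulate uneven
illumination, depth-dependent blur, autofluorescence or embryo-roll
(rotation about the body axis), so passing tests say nothing about those
failure modes.

In the validation experiment the atlas organ masks are grown by 3% in area
(exact Euclidean-distance growth) before transfer, mirroring the practice
of drawing reference masks slightly larger than the organ so that the
Simpson coefficient reads as "fraction of the organ correctly covered".

## Experiment sizes

The self-validation experiments (`zebreg.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use 10 seeded
replicates per stochastic experiment — 10 phantoms for registration, spot
recovery and bleed-through, 10×200 candidates for minimizer dominance, 50
images for the Otsu oracle — sizes at which the observed means are stable
to well within the asserted margins while the whole set completes in about
a minute.

## Known limitations

* Single embryo per image (largest component wins); no illumination
  correction; no z-stacks (maximum projection is assumed done upstream).
* Landmark correspondence is index-based along the contour; embryos
  differing grossly in pose (e.g. strongly curled) will mis-correspond.
* The TPS is not guaranteed diffeomorphic; at extreme λ→0 with
  conflicting landmarks the warp can fold. No fold detection is performed
  on fitted registrations (only on phantom ground-truth deformations).
* Spot detection reports masks, centroids and areas only — no sub-pixel
  localization, intensity quantification or cross-day tracking.
* Exclusion zones are fixed arc fractions, a proxy for the anatomically
  defined tail/yolk regions.
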