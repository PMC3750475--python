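# zebreg

Registration and per-organ quantification of zebrafish embryo microscope
images, for studies that inject fluorescently labeled tumor cells into
embryos and follow their spread over days. Zebrafish embryos at the same
developmental stage share a very similar outline, so one embryo can serve
as a *reference*: an expert marks its organs once (brain, eye, otic
vesicle, pectoral fin, yolk, ventral and dorsal somites), and every other
embryo is registered to it, inheriting those organ masks. Cancer burden is
then reported as the fraction of each organ's area covered by detected
fluorescent spots — per fish, per day, per organ.

## Method

The pipeline has four stages:

1. **Outline segmentation.** The embryo body is extracted from the green
   fluorescence channel (or an inverted DIC image) by Otsu thresholding
   OR-combined with zero-crossing edges of a 13×13 Laplacian-of-Gaussian
   filter (σ = 2), morphological closing with a disk of radius 25 px,
   largest-connected-component selection and hole filling. The outline is
   traced with the Moore-neighbor algorithm, clockwise from the
   topmost-leftmost boundary pixel.

2. **Contour landmarks.** The head and tail are the contour points with
   the largest pairwise distance (head = the wider end). Corresponding
   landmarks for reference and target fish are placed at equal arc-length
   intervals along both outlines (default 17), skipping the tail and yolk
   arcs whose shape varies too much between individuals; extra manual
   pairs (e.g. organ centers) can be appended from a CSV.

3. **Thin-plate-spline registration.** With target landmarks `p_i`,
   reference landmarks `q_i` and weights `σ_i = 1`, the mapping
   `f(x) = a₀ + a₁x₁ + a₂x₂ + Σᵢ wᵢ U(‖x − pᵢ‖)`, `U(r) = r² log r`,
   minimizes

   `J(f) = Σᵢ ‖qᵢ − f(pᵢ)‖²/σᵢ² + λ·E(f)`

   where `E` is the bending-energy quadratic form `wᵀKw` and λ = 300 by
   default. The closed-form solution is a bordered linear system; the same
   solver fits both directions, so atlas masks are pulled onto the target
   grid and target images can be resampled onto the reference grid without
   holes.

4. **Spot detection and quantification.** The red channel (optionally
   corrected for green bleed-through, `I = R + βG` with β estimated by
   least squares) is decomposed with the undecimated à-trous wavelet
   transform (kernel `[1/16, 1/4, 3/8, 1/4, 1/16]`, dilated with
   `2^{i−1} − 1` zeros per level). Spots persist at all scales, so pixels
   whose detail coefficients exceed `k·MAD/0.6745` at every level and whose
   multiscale product `P_J = Πᵢ Wᵢ` is positive are kept as spots.
   Registration quality is scored with the Simpson overlap coefficient
   `|A∩B| / min(|A|, |B|)`; coverage tables report per-organ spot
   fractions and can be averaged across fish.

A synthetic phantom generator (`zebreg.phantom`) produces fish-shaped
two-channel images with known organ masks, known smooth deformations and
known spot positions, so the entire pipeline is testable without
microscope data.

## Worked example

Generate a phantom pair (reference atlas + deformed target with injected
spots), register, detect spots and quantify:

```sh
zebreg simulate --seed 11 -o phantom/
zebreg register phantom/target_green.tif --atlas phantom/atlas \
    --masks-out masks/ --report report.json
zebreg spots phantom/target_red.tif --green phantom/target_green.tif \
    --bleedthrough -o spots.png --table spots.csv
zebreg quantify --masks masks/ --spots spots.png --fish F1 --day 1 -o coverage.csv
zebreg validate --registered masks/ --truth phantom/truth_organs -o overlap.csv
```

Output printed by the commands above:

```
phantom (seed 11) -> phantom/
registered with 17 landmarks; mean residual 0.06 px
bleed-through beta = 0.2520
10 spots detected
coverage for 7 regions -> coverage.csv
mean Simpson coefficient: 0.833
```

The fit report gives the mean landmark mismatch after registration
(`0.06 px`: at λ = 300 on a ~1000 px fish the fit is close to
interpolating). The estimated bleed-through coefficient `0.2520` recovers
the phantom's true β = 0.25, and all 10 injected spots are found.
`overlap.csv` lists the Simpson coefficient per organ — `0.833` mean means
the transferred organ masks largely cover the true (deformed) organs;
small organs (otic vesicle, pectoral fin) score lowest, and adding manual
center landmarks for them (`zebreg correspond --manual`) raises their
overlap markedly.

## Atlas directory layout

```
atlas/
  reference.tif          # reference embryo image
  brain.png eye.png ...  # one 0/255 mask per organ, same shape
  # or: labels.png (integer labels) + labels.csv (label,name)
```

Landmark CSVs have the header `target_row,target_col,ref_row,ref_col`, one
pair per line, in `(row, col)` pixel coordinates (origin top-left).

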