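# Methods

## Problem and model

A row-planted maize field at the three-leaf stage is surveyed with nadir
UAV frames. Planting follows a near-regular grid: parallel rows at a
nominal spacing (default 65 cm) with plants at a nominal in-row spacing
(default 25 cm). A planting position either emerges or stays empty; the
quantity of interest is the number (and location) of empty positions per
image. The counting chain assumes:

* rows are straight within a frame (no curved-row model);
* green vegetation is separable from soil by the excess-green index
  `ExG = 2G − R − B` — valid on bare-soil seedbeds, degraded by green
  cover crops or heavy residue;
* the in-row spacing is locally constant, so the mode of the consecutive
  projected inter-plant distances identifies the sowing spacing even when
  emergence gaps inflate some distances to (approximate) multiples of it.

The expected stand of one row is `round(D_d / D_t) + 1` where `D_d` is
the span of the plant projections along the fitted row line and `D_t` the
estimated spacing. This span-based count has a structural blind spot:
a gap *beyond the first or last emerged plant* of a row does not change
`D_d` and is invisible. The ground-truth container therefore exposes both
`n_missing` (all empty positions) and `interior_missing()` (empty
positions strictly inside the emerged span); verification compares the
pipeline against the latter, which is the quantity the method estimates.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `gsd_px_per_cm` | 2.3 | image scale, px per ground cm |
| `kernel_px` | 5 | closing element (square), px |
| `min_area_frac` | 0.02 | blob area cutoff, fraction of (plant spacing px)² |
| `step_px` | 10 | spacing-candidate grid step, px |
| `tolerance` | `0.2·median(D_i)` | match window of the mode search, px |
| `gap_factor` | 1.5 | `D_i > gap_factor·D_t` defines a gap interval |
| `min_row_members` | 4 | clusters smaller than this are not rows |
| `spacing_source` | `estimated` | `estimated` uses the mode search; `rated` uses plant_spacing_cm × gsd |

Rounding in the expected count is fixed to half-up (0.5 → 1) and recorded
in every report. Coordinates are raster convention (x right, y down,
0-based), boxes half-open.

### Spacing estimate: grid mode plus window mean

The candidate grid runs from `min D_i` to `max D_i` in 10-px steps; ties
in the match counter break toward the *smallest* candidate, which biases
toward the unit spacing rather than its multiples across gaps. Because
the match window (≈ 11 px at the default spacing) is wider than the
candidate step, several adjacent candidates often tie near the true
spacing, and the smallest-winner rule then returns a value pulled toward
`min D_i` — up to ~half a window low. The reported estimate `refined_Dt`
therefore averages the `D_i` inside the window around the winning
candidate; this removes the grid quantization (observed error < 1 px on
noise-free fields, < 4 px under 1 cm placement jitter) and is what the
expected count uses by default. The raw grid mode is kept in
`SpacingEstimate.chosen_Dt` and is the quantity checked against the
exhaustive-enumeration oracle.

### Row grouping

The dominant row direction is selected by scanning candidate angles (the
two principal axes of the centroid covariance plus a 1° sweep) and
scoring the 1-D clustering of the perpendicular coordinate: clusters are
split where the sorted-coordinate gap exceeds half the expected row
spacing, angles whose clusters are wider than 0.6 × the row spacing are
penalized as merged, and among the valid angles the fewest clusters (then
the lowest within-cluster variance) win. With at least 8 centroids, a
density screen first sets aside points with fewer than 3 neighbors
within 0.15 × the row spacing in the perpendicular coordinate: plant
rows are dense bands, inter-row weeds are not, and without the screen a
single weed midway between two rows can bridge them into one cluster.
Screened points return as singleton groups (the output stays a partition
of the input) and are dropped by the `min_row_members` rule, so they are
excluded from both the detected total and the spacing pool.

### Vertical-row guard

Rows are fitted by ordinary least squares of y on x. When the x-spread
of a group falls below half its y-spread the transposed model x(y) is
fitted and flagged — OLS of y on x is ill-conditioned for near-vertical
rows, while moderately slanted rows (up to slope ≈ 2) keep the
conventional orientation.

## Synthetic fields

The generator emulates what the counting chain must cope with, not
photorealism: a speckled soil background; each plant as three elliptical
leaf lobes plus a stem disk, hue-jittered within the HSV green band, at
its (optionally jittered) grid position; i.i.d. emergence dropout over
*all* positions; weeds as 1–2-lobed green blobs of 30–60 % plant area
placed between the rows (at least 0.2 × row spacing from any row line,
0.8 × plant spacing from any plant); a multiplicative illumination ramp
in a random direction; optional Gaussian blur and additive sensor noise.
Ground truth (positions, boxes, row lines, dropped slots) is exact by
construction, and generation is bit-reproducible from the spec seed.

Study conditions used by the verification suite: 2–6 rows, 8–15 plants
per row, dropout drawn from 0–30 %, placement jitter σ = 1.0 cm (≈ 4 %
of the 25 cm spacing — typical precision of mechanical seeders), noise
σ = 4 intensity levels, blur σ = 0.6 px, weed expectation 6 per frame on
the weedy half. The default scale is 2.3 px/cm (≈ 57 px between plants);
the coarse survey figure of 0.44 appears in the presets under both unit
readings (px/cm and its inverse) since either convention occurs in field
reports, and neither is asserted.

What the synthetic fields do **not** model — and hence what passing
tests cannot claim about real data: canopy overlap between neighbors at
later stages, within-row weeds, perspective and stitching distortion,
soil moisture/residue variation, and multi-date phenology.

## Detector architecture accounting

The architecture module is a structural artifact: it builds, runs a
forward pass, and is measured; it is not trained (no field dataset ships
with the package, and the counting chain uses segmentation centroids as
its default detector). Implementation is a small NumPy layer framework;
parameters are counted as trainable scalars, and FLOPs as 2 × the
multiply-accumulates of conv/linear layers at the configured input size
(the convention of the common detection profilers; norm layers,
activations and attention matrix products are excluded).

Calibrated constants of the maize variant (fixed in `ArchConfig`, not
searched at runtime): backbone truncated after the stride-16 stage with
`SPPF(128→256)`; the attention block at dim 256 = pre-LayerNorm + qkv
projection (bias-free) + output projection (with bias), 262,912
parameters; SC blocks with split ratio α = ½, squeeze ratio r = 2,
group-wise 3×3 with 2 groups, bias-free convolutions, GroupNorm(16);
head widths 32/64/128 at strides 4/8/16. With one class these choices
give 3,011,027 trainable parameters (3.01 M) / 8.1 GFLOPs for the
baseline and 1,185,939 (1.19 M) for the maize variant, with the
intermediate ablation combinations (head-only 1.04 M, head+attention
1.31 M, head+SC 0.92 M, SC-only 2.63 M) following from the same
constants. The neck wiring of the stride-4 branch uses the standard
P2-extension pattern (upsample the stride-8 neck output, concatenate the
stride-4 backbone feature, fuse, then re-descend).

Numerical notes: forward passes run in float32 on a single image
(channel-first); convolution is im2col + matmul; batch-norm layers run in
inference mode with unit statistics; weight initialization is
He-normal from a seeded generator, so fixed weights + fixed input give
bit-identical outputs. The routing attention gathers whole regions, so
with `top_k` = all regions it reproduces dense attention exactly (tested
to 1e-5 in float32).

## Verification design

Every estimator with a nontrivial decision rule is paired with an
independent brute-force oracle in the tests: Otsu vs a full 256-split
variance scan (compared on achieved variance and the induced mask, since
empty histogram gaps create exact ties that different argmax orders
break differently); blob centroids vs pixel means; OLS vs the normal
equations; the spacing mode vs exhaustive grid enumeration; greedy box
matching vs exhaustive assignment on separated fixtures; all-points AP
vs fine-grained Riemann integration of the interpolated PR curve; routed
attention vs dense attention.

Stand-count recovery is asserted over 100 seeded fields: exact recovery
of the emerged count and the interior missing count on ≥ 95 % of clean
fields (no jitter/noise/weeds), within ±1 per image on ≥ 95 % of
jittered weed-free fields, and the spacing estimate within
±(grid step/2 + jitter) px of truth on ≥ 95 % of all fields.

## Known limitations

* End-of-row gaps are invisible to the span-based expected count (see
  above); plot-level totals under-count when field edges fail.
* Touching canopies merge into one blob; the chain under-counts dense
  late-stage stands. The area filter separates specks, not plant-sized
  weeds — those are rejected only by failing to align into rows, so
  within-row weeds bias counts.
* The illumination model is multiplicative and monotone across the
  frame; ExG is robust to it, but color casts (e.g. strong shade/HDR
  seams in stitched mosaics) are not modeled.
* The spacing mode search assumes one dominant spacing per image; mixed
  sowing densities in a single frame violate it.
* Architecture claims are structural (budgets, shapes, block algebra);
  nothing here validates detection accuracy of the untrained network.
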