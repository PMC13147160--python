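# Methods

## Motility metrics

All three statistics operate on binary masks in a fixed raster convention:
(row, col) indexing, origin top-left, pixel `(r, c)` centered at
`((c + 0.5)·s, (r + 0.5)·s)` for pixel size `s` (µm/px, default 0.25 — a
typical 40× objective scale; configurable everywhere and never hard-coded in
the metrics). When no pixel size is supplied, outputs are emitted in px
units and flagged as such.

**Cell deformation area.** `A_CD = |{p : p ∈ C_{t+1}, p ∉ C_t}| · s²` on
superimposed masks. The symmetric counterpart (area lost) is the same call
with the arguments swapped; for integer-pixel translation gained = lost
exactly, which the tests assert. The quantity is evaluated at
non-overlapping 3-min boundary pairs — frames (0, 9), (9, 18), … for 20-s
frames — rather than sliding windows, keeping per-pair values
non-overlapping in time. A 60-frame recording therefore yields 6 complete
pairs and leaves 5 trailing frames unused by design.

**Centroid displacement.** Euclidean distance between unweighted
foreground-pixel-center means at the same boundary pairs.

**Circularity.** `P²/(4πA)`; equals 1 for an ideal circle and grows with
contour irregularity. Note the directionality caveat: with this formula,
rounded-up (cold-suppressed) cells have circularity *near 1* and irregular
amoeboid cells have *larger* values. Cohort tables report the index exactly
as defined; no re-interpretation is applied.

**Perimeter estimation.** Naive boundary-pixel counting biases circularity
of rasterized disks ~8% above 1 and was rejected. The default estimator
(`smooth_contour`) measures the length of the 0.5 iso-contour of the binary
mask smoothed with a sigma = 1 px Gaussian — a sub-pixel level set that
suppresses rasterization staircase. Measured accuracy per shape class:
disk r = 50 px perimeter +0.3% (circularity +0.9%); 100-px square
circularity −1.7%; 2:1 rectangle −1.1%; 10-px square perimeter −8.5%
(corner rounding dominates small axis-aligned shapes). Rasterized disks can
fall up to ε ≈ 0.02 below circularity 1. A Crofton 4-direction estimator is
available as an option (accurate for smooth shapes, ~5% low on axis-aligned
perimeters); the estimator name is recorded in the run manifest. Circularity
is exactly pixel-size-invariant since `s` cancels.

## Inclusion criteria

Cells enter the cohort only if they (a) are present in every frame of the
recording, (b) never touch the raster border, and (c) never come within
2 px (Chebyshev) of another cell — operationalized as unit dilations of both
masks not intersecting, i.e. a ≥ 3 px center gap passes. Components and
adjacency use 8-connectivity throughout. Tracks are linked frame-to-frame by
maximal mask IoU, ties broken by centroid distance then label. Excluded
tracks retain per-criterion flags for the inclusion report; the filter is
idempotent and order-independent. The pipeline reports *all* eligible cells;
subsampling to a fixed n is left to configuration.

## Synthetic amoeboid-cell generator

The generator provides ground truth for the full mask pipeline, not
photorealism. Each cell is a polar contour
`r(θ,t) = R(1 + Σ_k a_k(t) cos(kθ + φ_k))`, k = 2..4 by default, each mode an
Ornstein–Uhlenbeck process with stationary SD `protrusion_amplitude / k`
and relaxation rate `protrusion_rate_per_min` (default 2 /min — membrane
remodeling on the ~30-s scale). Mode k = 1 is excluded so the programmed
walk position remains the contour centroid to first order and can serve as
centroid ground truth. Radii are clamped at 0.2 R with a warning if the
amplitude would invert the contour. The centroid performs a persistent
random walk: deterministic step length `v·Δt` (so the frame-to-frame speed
is exactly the configured mean) and Gaussian heading turns of SD
`(1 − persistence)·π`; persistence = 1 is the exact ballistic limit.

Defaults mirror the acquisition contract of the experiments being emulated:
60 frames at 20 s (20 min total), 0.25 µm/px, base radius 5 µm (~10-µm
T cell), speed 2 µm/min, persistence 0.5, protrusion amplitude 0.2.
Randomness derives from one root seed via
`SeedSequence((seed, cell_index, stream))` child streams (shape / path /
placement), so adding a cell never changes earlier cells and identical
config + seed is bit-identical.

Rasterization places each cell's whole trajectory at a random offset such
that movie-long footprints, dilated by 2 px, never intersect — generated
cohorts therefore always pass the inclusion filter (the filter itself is
tested against deliberately proximate fixtures). An overcrowded field fails
with an explicit error after bounded retries. Ground truth records the
programmed centroid path and, per consecutive frame pair, the true polygon
set-difference area computed geometrically (shapely), independent of
rasterization.

What the generator does **not** emulate: optics (PSF, defocus, z-stacks),
intensity noise or segmentation ambiguity, cell–cell and cell–APC contact,
division/death, drift. Passing tests therefore validate the measurement
chain (rasterized masks → tracking → metrics → statistics), not robustness
to segmentation error on real micrographs.

## Cohort statistics

Welch's t-test (two-sided, Welch–Satterthwaite df, via scipy) on per-cell
summary means; stars at strict thresholds 0.05/0.01/0.001/0.0001; fold
change = ratio of group means, undefined (error) for a non-positive
reference. Summaries report mean ± SD; SEM appears only in flux time-course
output. No multiple-testing correction is applied across temperature panels
— each panel is tested alone, matching per-panel reporting practice; treat
cross-panel significance patterns with care. Degenerate input (both groups
constant and equal) returns t = 0, p = 1 with a warning. The null rejection
rate at α = 0.05 is asserted within [0.02, 0.09] over 500 simulated pairs.

## Extracellular-flux parameterization

Phase levels per well follow mito-stress-test report conventions: last basal
cycle, minimum post-oligomycin cycle, maximum post-FCCP cycle, mean of
rotenone/antimycin A cycles (a mean-of-phase alternative is provided; the
rule used is carried in the output). Derived parameters: nonmito = rotAA;
basal = basal − nonmito; proton leak = oligo − nonmito; ATP-linked =
basal − oligo; maximal = FCCP − nonmito; spare = maximal − basal (absolute
and as % of basal). The identity ATP-linked + proton leak = basal holds by
construction and is asserted on random traces. Protein normalization divides
all level-derived parameters by µg protein per well (the percent spare
capacity is scale-free). Negative spare capacity is reported with a warning,
never clamped, so bad wells remain visible to QC. Cycle counts per phase are
configuration (default 3) — real assays vary. Time courses report mean ±
SEM across wells; summary parameters mean ± SD with Welch comparisons.

## DE summary rules

Genes are classified up/down/ns by |log2FC| ≥ 1 (inclusive) and BH-adjusted
p < 0.05 (strict) — bounds exactly as conventionally printed. BH adjustment
uses the statsmodels step-up implementation, cross-checked in tests against
a brute-force oracle over exhaustive 6-element p-grids. "Detected genes" are
the rows of the input table; no independent expression filter is applied.
Row Z-scores for heatmap display use the sample SD (n − 1) and clamp to ±2;
constant rows become zeros with a warning. Volcano coordinates floor zero
adjusted p-values at one tenth of the smallest nonzero value and flag the
floored genes.

The DE generator spikes `n_up`/`n_down` genes at |log2FC| ≥ `lfc_effect`
(> 1 required) with p ~ 10^−U(8,30); null genes get |log2FC| ~ N(0, 0.3) and
uniform p. A null gene then passes the joint rule with probability ~6·10⁻⁶,
so spiked counts are recovered exactly with high probability and the
one-decimal percentages are insensitive to occasional stragglers.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately compact
problems chosen to exercise every code path at full fidelity: cohorts of
10–20 cells per condition (matching the n = 10–15 per-condition design of
the experiments emulated), 60-frame movies on 512² fields, 5 wells per flux
condition, 15,234-gene DE tables, 500-pair null calibrations. Floating-point
identities are asserted to 1e-9–1e-12; exact pixel-count identities (set
differences, BH vs oracle at 1e-12) exactly. Contours are sampled at 96
vertices; polygon rasterization uses scikit-image's scanline fill.

## Known limitations

- No drift/registration correction: the field is assumed stationary.
- Tracking is overlap-based; it requires frame-to-frame IoU > 0 and will
  fragment tracks of cells moving more than a cell diameter per frame.
- The circularity directionality caveat above.
- Flux phase detection trusts the phase labels in the input table; injection
  timing is not inferred from the trace.
- Absolute µm-scale agreement with any particular microscope depends
  entirely on the supplied pixel size; none is inferred.
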