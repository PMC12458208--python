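# Methods

This note documents the models, parameters and numerical choices behind
`isletrings`: what the synthetic tissue emulates, how each analysis stage
works, and what passing the recovery benchmarks does and does not show
about real slides.

## Synthetic tissue model

A section is a rectangle inset 100 µm from the image border (ragged tissue
masks are out of scope). Within it:

**Islets.** `n_islets` polygons are placed by dart throwing with an
effective-radius disjointness check (islet–islet gap ≥ 25 µm, ≥ 200 µm
clearance from the image border where the image allows it); a bounded
attempt budget turns infeasible requests into an explicit
`InfeasibleGeometryError`. Shapes are circles whose radius is modulated by
radial harmonics of order 2–5 with total relative amplitude
`islet_shape_irregularity` (default 0.15) — enough to look "islet-shaped"
without modelling real morphology. Each islet is insulin-containing (ICI)
with probability `ici_fraction`, otherwise insulin-deficient (IDI).

**Cells.** Cell centres form a hard-core point process: a Poisson-drawn
count at `cell_density_per_mm2` placed by grid-accelerated dart throwing
with minimum spacing `min_spacing_um` (default 7 µm; validated to be at
least 1.5× the minimum nucleus radius). A hard-core process was chosen
over richer point-process models because it keeps watershed-separable
nuclei and O(n) generation. The default density of 2,500 cells/mm² is a
deliberate desk-scale choice; the whole-tissue recovery benchmark instead
uses the density implied by the published percentage and absolute CD68+
density of the most infiltrated group (≈ 9,957 cells/mm², with spacing
6 µm and nucleus radii 2.0–2.9 µm so nuclei never physically overlap).

**Zones and marker states.** Each cell's zone is derived from its exact
(shapely) distance to the nearest islet boundary: `islet` inside,
optionally `peri` within 10 µm, `ring1`–`ring8` in 25 µm bands to 200 µm,
`exocrine` beyond. CD68 positivity is Bernoulli with the zone's configured
probability. The optional `peri` key exists because the 0–10 µm collar is
a sub-band of ring 1: the published collar and ring-1 percentages cannot
both hold on one tissue, so recovery runs use two sections (one with a
collar override, one homogeneous across ring 1). Inside ICIs, 65% of
non-macrophage cells are beta cells (insulin+). Per-islet HLA-II+
fractions for macrophages and beta cells come from a Gaussian copula with
Beta(μ·κ, (1−μ)·κ) marginals, κ = 20, and latent Pearson correlation
2·sin(π·ρ_S/6), giving exact Spearman-scale control; macrophages outside
islet+collar zones use the global mean fraction.

**Rendering.** Per channel, pixel background noise N(bg_mean, bg_sd) on
the 8-bit range, then soft-edged (0.6 µm ramp) max-blended blobs: nuclei
as mildly eccentric ellipses (axis ratio 0.85–1.0) on the nuclear channel;
CD68/HLA-II disks of radius `nucleus_radius + 5 µm` at positive cells;
insulin as a diffuse fill (25 grey levels) over each ICI plus brighter
disks (radius `nucleus_radius + 4 µm`) at beta cells, all clipped at the
islet boundary because insulin does not extend beyond the islet. Per-cell
amplitudes are drawn from N(fg_mean, fg_sd). All draws descend from one
`SeedSequence`, so identical configurations reproduce bit-identical pixels
and tables (chunked noise generation preserves the draw order).

What the generator does **not** emulate: autofluorescence and tissue
texture, staining gradients and batch effects, vasculature and ducts,
lobular heterogeneity, segmentation-hostile cell shapes, and z-stack
artefacts. Passing recovery benchmarks therefore validates the *analysis
logic* — geometry, counting, statistics, and the detector/classifier
contracts under the stated intensity model — not robustness to real-slide
image quality.

## Detection and cell expansion

Nuclei: Gaussian smoothing (σ = 1.5 µm default; 1.0 µm for the
high-density benchmark sections), triangle threshold (or a fixed value),
connected components, then per-component watershed. Watershed markers are
h-maxima of the *smoothed intensity* (depth 10 grey levels) rather than of
the distance transform: merged nuclei keep distinct intensity peaks long
after their distance-transform ridge flattens, which measurably improves
recall on touching pairs; the flooding itself runs on the negated distance
transform so boundaries fall at the waist. Area bounds 10–400 µm². Cell
ids are assigned in raster order of nucleus centroids, making every
downstream table deterministic. Detection counts are monotone
non-increasing in the threshold once it exceeds the background plateau; at
near-background thresholds a merging component can occasionally split and
raise the count by one.

Expansion by `cell_expansion_um` (default 5 µm) is a distance-limited
nearest-nucleus assignment (`expand_labels`), i.e. dilation clipped
against neighbours along the equidistant line, computed in 2,048-row bands
so the distance transform never spans a whole slide. Features are mean
intensities per compartment (nucleus, cell, cytoplasm = cell − nucleus;
empty cytoplasm is recorded as missing).

## Classification

Two model families behind one interface: fixed thresholds on a chosen
compartment (default: whole-cell mean for all three markers), and seeded
random-forest ensembles (50 trees, depth ≤ 8) over all per-compartment
channel means. The pipeline default trains the forest on ground-truth
labels of detections matched within 5 µm — the synthetic stand-in for an
annotator-trained object classifier — and falls back to the
intensity-midpoint threshold when a marker has fewer than 20 matched
examples of either class. Per-channel minimum-intensity floors (99.5th
percentile of background, defined as pixels beyond 5 µm of any nucleus)
veto positive calls that do not clear background. Composite calls are
conjunctions, so the subset laws (CD68+HLA-II+ ⊆ CD68+ ∩ HLA-II+) hold by
construction.

## Region geometry

ICI segmentation: smooth the insulin channel (σ = 2 µm), triangle
threshold, morphological closing (radius 5 µm, banded distance-transform
implementation), hole filling, then a boundary-refinement erosion equal to
the smoothing σ. The refinement compensates a systematic outward shift:
with a threshold far below the islet interior level, the blurred boundary
crosses it roughly one σ outside the true edge, which would bias every
distance-band statistic around the islet (measured residual dilation after
refinement: ~1 µm, area ratio ≈ 1.04, mean IoU ≈ 0.96 against truth).
Components below 1,000 µm² are discarded. IDIs enter from GeoJSON (or the
generator's truth); an IDI overlapping an ICI is an error.

Collars and rings are shapely buffers (quad_segs = 24, chord error
≪ 0.25 µm at relevant radii) minus all islet interiors, clipped to the
tissue polygon. Overlaps between neighbouring islets' territories are
resolved by a nearest-boundary rule: the shared region is partitioned by a
Voronoi diagram of both boundaries densified at 2 µm, ties to the lower
region id; pairs are processed in sorted id order, so triple overlaps
resolve sequentially (deviation from the exact rule is confined to
measure-zero slivers at the densification scale). Geometry operations fall
back to coverage unions / precision-snapped overlays when GEOS reports
topology conflicts. The alternative of leaving expanded regions
overlapping was rejected because adjacent islets would double-count cells
and inflate collar percentages.

Cell-to-region assignment uses the nucleus centroid and closed polygons
(boundary counts as inside) via an STRtree; within a family, the islet
wins over its collar and the inner ring over the outer, ties to the lower
region id. Exocrine squares (500 µm side, 15 per section at whole-slide
scale) are placed by seeded rejection sampling avoiding islets and
collars; outer rings may overlap exocrine squares because the two analyses
are independent passes.

## Statistics

`compare_groups` gates on Shapiro–Wilk per group at α = 0.05 (a constant
group counts as non-normal): all normal → one-way ANOVA + Tukey HSD;
otherwise Kruskal–Wallis + Dunn's z tests with Bonferroni adjustment
(capped at 1). Kruskal–Wallis uses the tie-corrected H and, for pooled
n ≤ 12, an exact permutation p computed by enumerating distinct
assignments of rank positions to groups. The two-way group×ring analysis
is an OLS fit with Sum-coded factors and type-III partial sums of squares
(region counts per group are never balanced), with per-factor Tukey
comparisons. Spearman correlation uses average ranks; its confidence
interval is Fisher-z with SE = sqrt(1.06/(n−3)) (closed form, standard for
rank correlations; empirical coverage ≥ 0.92 at n = 100 in the suite) and
the p-value the t approximation. Pooling per-region observations across
donors replicates the source design; donor-clustered inference is
deliberately out of scope.

Regions with zero cells contribute **missing** percentages, not zeros —
0/0 is undefined and a zero would bias group comparisons of sparse
regions. Density maps grid positive centroids (50 µm cells), convert to
mm⁻², Gaussian-smooth (100 µm bandwidth) and mask outside the tissue; at
zero bandwidth the grid mass equals the positive count exactly.

## Benchmark problem sizes

Recovery runs are sized so that binomial noise sits well inside each
tolerance while one section fits comfortably in desk memory: the
whole-tissue benchmark uses one ~1.7 mm section at 0.325 µm/px with
≥ 20,000 cells; the zone-profile benchmarks use 6×6 mm sections at
0.65 µm/px with 350 islets (220 islets at 4.7 mm inside the test suite),
~120,000 cells and ~5,000 collar cells pooled; the co-expression
benchmarks draw 500 islet pairs directly from the copula. The coarser
pixel size for many-islet sections is a deliberate trade — nuclei stay
5–7 px wide, detection F1 remains ≥ 0.99 — and pixel size stays a free
config parameter with 0.325 µm as the default.

## Known limitations

- The intensity model is far cleaner than real immunofluorescence;
  absolute classifier thresholds mean nothing off-simulator.
- The boundary-refinement erosion is calibrated to the rendering model's
  edge profile; on other stain distributions the refinement radius should
  be re-examined.
- `segment_islets` recovers only insulin-containing islets; IDI geometry
  must be supplied.
- Two-tier ("high") marker expression is not modelled: a single positive
  class per marker stands for high expression throughout.
- Very high densities (> ~12,000 cells/mm² at 6 µm spacing) approach the
  hard-core packing limit and slow generation before detection degrades.
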