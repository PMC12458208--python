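# isletrings

Spatial quantification of macrophage infiltration around pancreatic islets
in whole-slide multiplex immunofluorescence images — with a seeded
synthetic-tissue generator that provides pixel-level ground truth for every
stage of the analysis.

## The problem

In type 1 diabetes, macrophages (CD68+ cells) accumulate in and around the
insulin-producing islets of Langerhans, and a subset of them upregulate
HLA class II, marking antigen-presenting activation. Quantifying this
infiltration on whole pancreas sections requires a chain of image-analysis
steps — nuclei detection on the nuclear stain, per-cell marker
classification (insulin, CD68, HLA-II, and their composites), islet
segmentation from the insulin channel, and distance-resolved region
geometry around each islet — followed by group-level statistics. Each step
has tunable parameters and failure modes that are invisible without ground
truth.

`isletrings` re-implements this pipeline as a tested, reusable library and
pairs it with a generator of synthetic four-channel sections
(Hoechst/DAPI, insulin, CD68, HLA-II; 8-bit; 0.325 µm/px by default) whose
cell positions, marker states and region geometry are known exactly, so
every stage can be validated by parameter recovery.

## What it computes

For each islet the package builds, in µm coordinates:

- the **islet region** itself (segmented from the insulin channel for
  insulin-containing islets, or supplied as GeoJSON for insulin-deficient
  ones);
- the **peri-islet collar**: the 10 µm band around the islet boundary;
- **eight concentric rings** of 25 µm width covering the 0–200 µm collar,
  where ring *k* of islet *i* is
  `(i ⊕ k·25 µm) \ (i ⊕ (k−1)·25 µm)` minus all islet interiors, clipped
  to the tissue and de-overlapped between neighbouring islets along the
  equidistant line between their boundaries;
- randomly placed **exocrine reference squares** (15 × 500 µm by default)
  avoiding islets and collars.

Cells are nuclei detected by smoothing + triangle threshold + marker-seeded
watershed, expanded 5 µm into Voronoi-clipped whole-cell territories. For a
region with `n` cells of which `n⁺(m)` are positive for marker `m`, the
package reports `pct(m) = 100·n⁺(m)/n` and `density(m) = n⁺(m)/area`
(per mm²), plus smoothed macrophage density maps. Group statistics follow
the standard histology battery: Shapiro–Wilk-gated one-way ANOVA/Tukey or
Kruskal–Wallis/Dunn (with an exact small-sample permutation null), two-way
group×ring ANOVA with type-III sums of squares, and Spearman correlation
with a Fisher-z interval, `SE = sqrt(1.06/(n−3))`.

The generator controls the islet-level co-expression structure with a
Gaussian copula: per-islet macrophage and beta-cell HLA-II+ fractions have
Beta marginals and latent Pearson correlation `2·sin(π·ρ_S/6)`, so the
target Spearman coefficient `ρ_S` is hit exactly in expectation.

## Worked example

```python
from isletrings import (TissueConfig, DetectionParams, RingSpec, ExocrineSpec,
                        generate_tissue, analyze_tissue, pooled_stats)

cfg = TissueConfig(image_size_px=(3000, 3000), n_islets=4,
                   islet_radius_um_range=(40, 70), ici_fraction=1.0, seed=1)
stack, truth = generate_tissue(cfg)           # 4-channel image + ground truth
result = analyze_tissue(stack, truth, DetectionParams(), RingSpec(),
                        ExocrineSpec(n_regions=2, side_um=200), seed=1)

w = result.whole_tissue
print(f"cells detected: {w['n_cells']}  (detection F1 {result.detection_score['f1']:.3f})")
print(f"whole-tissue %CD68+: {w['pct_cd68']:.2f}   density: {w['density_cd68']:.0f} /mm^2")
for cls in ("islet_ICI", "peri_islet", "ring_1", "ring_8"):
    p = pooled_stats(result.stats, cls)
    print(f"{cls:11s} cells={int(p['n_cells']):5d}  %CD68+={p['pct_cd68']:.2f}")
```

prints

```
cells detected: 1493  (detection F1 0.997)
whole-tissue %CD68+: 9.38   density: 233 /mm^2
islet_ICI   cells=  110  %CD68+=10.00
peri_islet  cells=   39  %CD68+=20.51
ring_1      cells=   95  %CD68+=16.84
ring_8      cells=  106  %CD68+=10.38
```

The 1 mm² demo section carries the default zone profile (19.6% CD68+ in
the 0–10 µm collar, 13.6% in ring 1, 6.2% inside islets, declining to 7.9%
in exocrine tissue); with only ~1,500 cells the per-zone estimates carry
binomial noise of 1–4 percentage points, which is why the recovery
benchmarks pool hundreds of islets.

A command-line interface mirrors the stages
(`isletrings simulate | detect | classify | regions | quantify | run |
experiment`); see `isletrings --help`.

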