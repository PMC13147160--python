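# coldmotility

Quantitative analysis of temperature-dependent T-cell motility from
time-lapse binary masks, with companion tools for mitochondrial
stress-test (Seahorse OCR/ECAR) parameterization and differential-expression
summaries — the measurement stack of a cold-acclimation experiment, built
for reuse and testing.

Crawling T cells slow down sharply below ~32 °C and round up, but cells
pre-cultured for ~24 h at a subphysiological temperature ("cold-acclimated")
retain amoeboid motility in the cold. Quantifying that phenotype needs three
per-cell statistics computed from segmented binary masks, cohort-level
comparisons, and the metabolic/transcriptomic readouts that accompany it.
This package implements all of those, plus a ground-truthed synthetic
amoeboid-cell generator so every stage can be validated end to end without
raw microscopy data.

## Statistics implemented

For a cell with binarized regions $C_t$ and $C_{t+1}$ at two time points
separated by 3 min:

- **cell deformation area** $A_{CD} = \mathrm{Area}(C_{t+1} \setminus C_t)$,
  the area newly occupied after the interval, computed on superimposed masks.
  For pure translation the gained area equals the lost area; asymmetry
  reflects spreading or contraction.
- **centroid displacement** $\lVert \bar{x}(C_{t+1}) - \bar{x}(C_t)\rVert$,
  the migration length of the mask centroid over 3 min.
- **circularity index** $= P^2 / (4\pi A)$ from each mask's perimeter $P$
  and area $A$: 1 for a circle, larger for irregular contours.

Intervals are non-overlapping 3-min boundary pairs: a 60-frame, 20-s-interval
recording (total imaging time 20 min) yields 6 complete pairs.

Cohorts are compared with Welch's *t*-test (two-sided, Welch–Satterthwaite
df), annotated `*`/`**`/`***`/`****` at p < 0.05/0.01/0.001/0.0001, with fold
changes as ratios of group means. Mito-stress-test traces (basal →
oligomycin → FCCP → rotenone/antimycin A) are reduced to basal respiration,
ATP-linked respiration, proton leak, maximal respiration and spare
respiratory capacity, optionally protein-normalized. DE tables are
classified by |log2FC| ≥ 1 and Benjamini–Hochberg FDR < 0.05, summarized as
counts/percentages, and prepared for volcano plots and row-Z-scored
(±2-clamped) heatmaps.

## Worked example

The bundled demo simulates four cohorts of 10 cells (60 frames, 20-s
intervals, 0.25 µm/px): non-acclimated and acclimated cells imaged at 37 °C
and 26 °C, with crawling speed and protrusion amplitude programmed per
condition (acutely cooled non-acclimated cells nearly immobile; acclimated
cells motile in the cold):

```sh
coldmotility demo --out demo_out --seed 1
```

prints the cohort comparison table (also written to
`demo_out/motility/comparisons.csv`):

```
                  label  mean_non-AC  sd_non-AC  n_non-AC   mean_AC    sd_AC  n_AC      p_value stars  fold_change
        37:mean_acd_um2    33.788542   5.197150        10 26.198958 4.970016    10 3.672485e-03    **     0.775380
37:mean_displacement_um     3.336233   0.604993        10  2.385126 0.526592    10 1.507345e-03    **     0.714916
    37:mean_circularity     1.156275   0.013814        10  1.079384 0.012226    10 1.338570e-10  ****     0.933502
        26:mean_acd_um2     4.200000   0.846536        10 28.296875 4.625248    10 2.703593e-08  ****     6.737351
26:mean_displacement_um     0.355894   0.047842        10  2.681664 0.457576    10 5.065890e-08  ****     7.535001
    26:mean_circularity     1.012843   0.000962        10  1.116441 0.008659    10 2.080065e-11  ****     1.102284
```

Reading the 26 °C rows: acclimated cells show a ~6.7-fold larger mean
deformation area and ~7.5-fold larger 3-min centroid displacement than
non-acclimated cells (both ****), while non-acclimated cells at 26 °C are
nearly circular (mean circularity 1.013) — the cold-acclimation phenotype
the metrics are designed to resolve. At 37 °C the programmed mild deficit of
acclimated cells is likewise detected. Per-cell values, per-pair long tables,
the inclusion report and a manifest (seed, units, estimator choices) are
written alongside.

Each simulated movie is also usable piecewise: `simulate_shape_series` /
`simulate_track` / `rasterize_movie` produce labeled TIFF stacks + JSON
sidecars with ground-truth centroid paths, `read_mask_stack` →
`build_tracks` → `filter_tracks` apply overlap tracking and the inclusion
criteria (full duration in field, never touching the border, ≥ 3 px from
neighbours), and `compute_motility` yields the per-cell record.

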