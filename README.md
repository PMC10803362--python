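# viadens — viable tumor cell density from point-annotated histology

After neoadjuvant chemotherapy, osteosarcoma response is conventionally
graded by the necrosis rate a pathologist estimates on the maximum cut
face. That grading is coarse and poorly reproducible, and it does not
count the cells that actually survived treatment. An alternative readout
is the **viable tumor cell density**: the number of viable tumor cells
detected across all slides of a case, divided by the pathologist-annotated
tumor area,

```
density = Sum / Area,   Sum = Σ_i Σ_k a_ik   [cells],   Area = Σ_i S_i   [mm²]
```

where `a_ik` is the detected cell count in patch *k* of slide *i* and
`S_i` the polygon area of slide *i*. `viadens` implements the full
analysis pipeline behind that readout, end to end and fully testable
without any real whole-slide image:

- **synthdata** — seeded generators for H&E-like patches (dark basophilic
  nuclei + pale necrotic/stromal distractors with exact ground-truth
  centers), tiled pseudo-slides with known planted counts inside a tumor
  polygon, and survival cohorts drawn from a proportional-hazards model
  with a planted density cut-off.
- **detect** — heatmap-regression nucleus detection trained from point
  annotations: Gaussian target maps (peak 1 per nucleus), squared-error
  loss, Adam, per-epoch model selection on validation F-measure, greedy
  peak extraction.
- **evalmetrics** — the detection evaluation protocol: one-to-one point
  matching within a 20 px radius (maximum-cardinality, minimum total
  distance), precision / recall / F-measure, and a patient-grouped
  five-fold cross-validation harness (3 train / 1 validation / 1 test
  subsets per fold).
- **density** — region tiling on a fixed grid, in-polygon counting with
  cross-seam deduplication, shoelace polygon area in mm², and pooled
  Sum/Area density per case.
- **survival** — stratification at a density cut-off (high = density ≥
  cut-off), Kaplan–Meier curves and log-rank tests for disease-specific
  and metastasis-free survival (DSS, MFS), univariate Cox hazard ratios
  with Wald 95% CIs, a 50/mm² cut-off scan with a dual-endpoint
  balance-based selection rule, a density-vs-necrosis cross-tabulation,
  and an exact Mann–Whitney rank-sum comparison.
- **io / cli** — versioned JSON/CSV/YAML formats, readers for annotator
  XML polygons and labelme-style point JSON, and a thin `viadens`
  command-line pipeline (`simulate | train | detect | evaluate | density |
  survive | report`).

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/03_slide_density.py` builds a pseudo-slide with exactly
100 nuclei planted in a 1 mm² annotated square (1 µm/px), then counts
them two ways:

```
slide raster 1024x1024 px, annotated area 1.000 mm², planted density 100.0/mm²
16 grid patches intersect the tumor polygon
oracle detector: Sum=100, Area=1.000 mm², density=100.0/mm²  (exact by construction)
trained detector: Sum=98, density=98.0/mm²  (2.0% from truth)
```

The oracle row shows that tiling, point-in-polygon filtering, seam
deduplication and Sum/Area pooling introduce no loss of their own; the
trained-detector row shows the detection stage adds only a small error on
this synthetic task. `python examples/04_survival_analysis.py` then
generates a 200-patient cohort with a planted 400/mm² cut-off and a
4.5-fold hazard in the high-density group, and recovers it:

```
scanned 19 cut-offs; significant on both endpoints: 50-700/mm²
selected cut-off (balance rule): 400/mm² (planted truth: 400/mm²)
DSS: HR=4.21 (95% CI 2.97-5.96, p=5.36e-16)
MFS: HR=5.31 (95% CI 3.66-7.70, p=1.18e-18)
```

The CLI runs the same stages from a YAML config, archiving the config
next to every stage's outputs:

```bash
viadens simulate --seed 11 --outdir run
viadens train    --outdir run
viadens density  --outdir run
viadens survive  --outdir run
viadens report   --outdir run
```

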