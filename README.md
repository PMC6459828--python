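# cartiq

Serial multiparametric quantitative MRI (qMRI) analysis of articular
cartilage under compressive loading, driven end-to-end by a synthetic
phantom cohort generator.

The pipeline mirrors an *ex-situ* cartilage loading experiment: disc-shaped
cartilage samples are imaged with four mapping sequences (T1 inversion
recovery, T1ρ spin-lock, T2 multi-spin echo, T2\* multi-gradient echo) at
three loading positions (unloaded `d0`, 2.5 mm `d2.5` and 5.0 mm `d5.0`
displacement). From the serial magnitude images the package fits per-pixel
relaxation-time maps, aggregates zonal means over the entire sample (ECS)
and its superficial (sf) / deep (dp) halves, computes per-sample loading
responses (Δ2.5 / Δ5.0), and runs the statistical and diagnostic battery:
repeated-measures ANOVA with Tukey post-tests, log-transformed unpaired
t-tests, Spearman correlations, noncentral-t power analysis, mean ± SD
reference-interval classification, and believe-the-positive /
believe-the-negative test combination.

## Modules

| module | purpose |
| --- | --- |
| `cartiq.protocols` | acquisition protocols (TI/TSL/TE schedules) and echo-exclusion rules |
| `cartiq.relaxometry` | signal models, pixel-wise mono-exponential / magnitude-IR fitting, adjusted-R² quality control |
| `cartiq.roizones` | boundary-pixel erosion, equal two-zone partition, caliper geometry, zonal statistics |
| `cartiq.response` | relative-change computation, tangent Young's modulus, tidy cohort table |
| `cartiq.stats` | normality check, repeated-measures ANOVA + Tukey, t-tests, Spearman, sample-size computation |
| `cartiq.diagnostics` | histology scoring, reference intervals, sensitivity/specificity, test combination |
| `cartiq.synthdata` | ground-truth phantoms, Rician-noise image rendering, stress–strain curves, cohort generation |
| `cartiq.io` / `cartiq.cli` | NIfTI/NPZ series I/O with JSON sidecars, overlays, command-line surface |
| `cartiq.pipeline` | cohort → maps → zonal records → cohort table glue |

## CLI

```bash
# generate a synthetic cohort (series + masks + metadata + curves)
cartiq simulate --out scratch/cohort --seed 1

# fit one series into a parameter map (with optional overlay PNG)
cartiq fit --series scratch/cohort/int000/T2_d0.npz \
           --mask scratch/cohort/int000/T2_d0_truth.npz \
           --out scratch/T2_map.npz --overlay scratch/T2_map.png

# erode + split a mask into superficial/deep zones, report caliper geometry
cartiq segment --mask scratch/cohort/int000/T2_d0_truth.npz --out scratch/roi.npz

# simulate + full imaging pipeline into a tidy cohort table
cartiq process --seed 1 --out scratch/run

# statistics, diagnostics, and group-summary tables from a cohort table
cartiq analyze  --table scratch/run/cohort.csv --out scratch/run
cartiq diagnose --table scratch/run/cohort.csv --out scratch/run
cartiq report   --table scratch/run/cohort.csv --out scratch/run
```

Cohort configurations are plain YAML mirroring
`cartiq.synthdata.CohortConfig`; a fixed seed makes every command
byte-reproducible.

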