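# stpower

Simulation-based sample-size and power analysis for compartment-targeted
spatial transcriptomics experiments (GeoMx-style regions of illumination on
liver tissue), with the models, calibration and data generators needed to run
the whole design loop on synthetic data.

## The problem

Suppose a bulk RNA-seq cohort shows that a gene moves by some log2 fold change
between clinical outcome groups, and a follow-up spatial experiment will probe
that gene inside one tissue compartment — hepatocyte areas or the fibrotic
niche — by profiling a handful of regions of illumination (ROIs) per patient.
How many patients and ROIs, and which ROI diameter, give adequate power?

Two features make the naive power calculation wrong:

* **Counts are overdispersed and clustered.** ROIs from the same patient share
  a random intercept; the right test vehicle is a negative-binomial mixed
  model (NB GLMM) with a log effective-library-size offset, not a t-test.
* **Compartment effects are diluted in bulk.** A fold change measured in bulk
  tissue understates the change inside a small compartment. The fibrotic
  niche covers only a few percent of the tissue, so reproducing a bulk log2FC
  requires a much larger within-niche perturbation than the same log2FC in
  the dominant hepatocyte fraction.

`stpower` handles both: a spike-in **calibration curve** translates a bulk
effect size into a compartment-level perturbation `r`, and a Monte-Carlo
**power engine** assembles synthetic ROI datasets from spot-level data and
tests the group effect with an NB GLMM fitted by adaptive Gauss–Hermite
quadrature.

## What is in the box

| Module | Contents |
| --- | --- |
| `stpower.synth` | Synthetic Visium-like spot grids (contiguous niche/hepatocyte compartments, NB counts) and a bulk fibrosis cohort with planted gene-set effects |
| `stpower.discovery` | Normalization (median-of-ratios / poscounts size factors), candidate endpoint screen, gene-set summary scores, percentile segmentation into compartments |
| `stpower.calibration` | Spike-in arithmetic, pseudobulk, paired NB fold changes, calibration curves and their inversion |
| `stpower.geomx` | Diameter→spot-count mapping, contiguous ROI sampling from spot pools, patient assignment, ROI dropout |
| `stpower.nbmodels` | TMM effective library sizes, NB GLM (profiled dispersion), NB GLMM (patient random intercept, AGQ), Wald and LRT group tests |
| `stpower.power` | Per-condition Monte-Carlo power, simulation grids, dropout sensitivity, sample-budget and alpha arithmetic |
| `stpower.readwrite` / `stpower.cli` | MTX/CSV readers and writers, end-to-end pipeline runner, `stpower` command line |

## Worked example

Simulate tissue, segment it, calibrate a spike-in to a bulk effect size, and
estimate power over patient counts (runs in a few minutes):

```python
import numpy as np
from stpower import (SimConfig, SpikeSpec, Condition, RunConfig,
                     generate_spot_dataset, normalize_counts, kuppe_score,
                     segment_spots, build_calibration_curve,
                     invert_calibration, apply_spike, restrict_to_class,
                     run_condition)

cfg = SimConfig(seed=11)                       # 5 samples, 60x60 spot grids
spots = generate_spot_dataset(cfg)
sets = cfg.resolved_marker_sets()

norm = normalize_counts(spots.counts, genes=spots.genes,
                        columns=spots.spot_meta.index,
                        size_factor_method="poscounts")
hep = kuppe_score(norm, sets["hepatocyte"], name="hepatocyte")
ecm = kuppe_score(norm, sets["ecm"], name="ecm")
seg = segment_spots(spots, hep, ecm)
print(seg.labels.value_counts().to_dict())
# {'hepatocyte': 12176, 'other': 4736, 'niche': 1088}

curve = build_calibration_curve(spots, seg, "PON1", "hepatocyte",
                                np.round(np.arange(0, 2.01, 0.1), 10))
r_star = invert_calibration(curve, 0.42)       # bulk-cohort log2FC target
print(round(r_star, 3))
# 0.598

spiked = apply_spike(spots, SpikeSpec("PON1", r_star, "hepatocyte"), seg)
pool_c = restrict_to_class(spots, seg, "hepatocyte")
pool_s = restrict_to_class(spiked, seg, "hepatocyte")

run = RunConfig(alpha=0.025, n_reps=100, seed=1)
for n_p in (4, 6, 10):
    cond = Condition("primary", n_p, 2, 165.0,
                     SpikeSpec("PON1", r_star, "hepatocyte"))
    res, = run_condition(cond, pool_c, pool_s, run)
    print(n_p, round(res.power, 2), round(res.median_lfc, 3))
# 4  0.74 0.572
# 6  0.92 0.525
# 10 0.96 0.558
```

Note the recovered within-compartment log2FC (~0.55) exceeds the bulk target
0.42: that is the dilution effect the calibration corrects for, here mild
because hepatocytes dominate the tissue. For a niche-targeted endpoint the
same bulk log2FC requires a several-fold larger `r`.

The same loop is available end to end from the command line:

```bash
stpower run-all --seed 0 --out results/demo
```

which writes the spot data, screen, segmentation labels, calibration curves,
power table and a manifest (master seed, config hash, alpha) under
`results/demo/`.

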