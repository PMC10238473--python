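# Methods

This note records the statistical models, the synthetic-data defaults and the
numerical choices behind `stpower`, in enough detail to audit or re-derive
them.

## 1. Count model and tests

### NB GLMM

For ROI counts `y_ij` of one endpoint gene (patient `i`, ROI `j`):

```
y_ij | b_i ~ NegBin(mu_ij, theta)            Var = mu + mu^2 / theta
log mu_ij = log(L_ij) + beta0 + beta1 * group_i + b_i
b_i ~ Normal(0, sigma_b^2)
```

`L_ij` is the effective library size (raw ROI total × TMM factor), entering
as a fixed offset. `beta1` is the natural-log group effect; reported fold
changes are `lfc = beta1 / ln 2`.

The marginal likelihood integrates `b_i` out per patient. We maximize it
directly over `(beta0, beta1, log theta, log sigma_b)` with L-BFGS-B, using
**adaptive Gauss–Hermite quadrature** (AGQ, default 15 nodes): for each
patient the integrand is centred at the conditional mode `b̂_i` (found by a
vectorized Newton iteration) and scaled by the square root of the negative
inverse Hessian, i.e.

```
log ∫ e^{h(b)} db ≈ log(√2 s_i) + logsumexp_k [ log w_k + z_k² + h(b̂_i + √2 s_i z_k) ]
```

with Gauss–Hermite nodes `z_k`, weights `w_k`. Bounds: `log theta ∈ [−7, 15]`,
`log sigma ∈ [−10, 3]`. When the optimizer drives `sigma` to its floor the
random intercept has vanished and the model is refitted as the exact NB GLM
(the two likelihoods agree to < 1e−6 there, one of the acceptance checks).

The quadrature is validated against a dense **trapezoid-grid oracle**
(±8 sigma, 2001 points) that shares no code with the AGQ path; agreement is
within 1e−3 over random small designs and typically 1e−6 or better.

Standard errors of `(beta0, beta1)` come from the numerically differentiated
2×2 observed-information block at the estimated variance parameters — the
same convention as lme4/glmmTMB, and verified against glmmTMB (nbinom2) to
~3 decimals on fixtures. glmmTMB's reported log-likelihood is a Laplace
approximation, so only parameters and SEs are compared tightly.

### NB GLM

The boundary model (and the pseudobulk fold-change engine) is an NB GLM with
log link: IRLS with step-halving at fixed `theta`, and `theta` profiled by
1-D bounded minimization over `log theta`. Wald SEs use the observed
information `w = mu·theta·(theta + y)/(theta + mu)²`. The fit matches
statsmodels' discrete `NegativeBinomial` (alpha = 1/theta) to ~1e−5.

### Tests

* **Wald**: two-sided normal test of `beta1 / se(beta1)`.
* **LRT**: full vs intercept-only GLMM (both with the random intercept),
  `chi²₁`. Negative statistics beyond −1e−6 mark non-convergence.
* **Plugin**: any callable `(y, group, patient, offset) -> TestResult`, the
  hook for alternative count tests.

Under the null at the default study condition (10 patients × 2 ROIs of 9
aggregated spots, α = 0.025), the Wald test's measured type-I rate over 1000
repeats is 0.034 — mildly anticonservative but inside the 99% binomial CI
around 0.025, and identical to glmmTMB's p-values on the same datasets.

### TMM effective library sizes

Trimmed mean of M-values, following the standard recipe: reference column =
the one whose upper-quartile/library-size ratio is closest to the mean such
ratio; per column, log2 expression ratios to the reference (M) are trimmed by
30% on M and 5% on average log expression (A) via rank windows, then averaged
with inverse-asymptotic-variance weights; factors are rescaled to geometric
mean 1. Verified against `edgeR::calcNormFactors` to 1e−6.

## 2. Calibration of compartment effects

A spike-in with fraction `r` adds `r × median(target-gene counts over the
target-class spots of that sample)` to every target-class spot, rounded
half-up (the median is taken over unmodified counts). Summing all spots per
sample gives pseudobulk; the paired NB fold change of the gene between spiked
and unmodified pseudobulk (sample fixed effects, shared median-of-ratios size
factors over all 2n columns) as a function of `r` is the **calibration
curve**. Inverting it at a bulk-cohort log2FC picks the `r*` that reproduces
that bulk effect; inversion interpolates linearly and returns the smallest
bracketing `r`.

Because the fibrotic niche is a few percent of spots while hepatocytes are
about two thirds, the same pseudobulk log2FC demands a several-fold larger
`r` for a niche endpoint — the dilution property, asserted in the acceptance
suite.

## 3. Synthetic data

The generators' defaults are the assumed study conditions; they were fixed
from the reference tissue characteristics before any power numbers were
looked at, and are not tuned to test outcomes.

### Spot-level tissue

* 5 samples on 60×60 grids of 55 µm spots at 100 µm centre spacing.
* Compartments: fibrotic niche target 5% of spots (±15% relative jitter per
  sample, keeping realizations within the 2.6–7.1% range observed in
  reference liver sections), hepatocyte target 65.5% (±4%), remainder
  "other". Compartments grow as contiguous random blobs (niche blob size
  10–40 spots), so percentile segmentation sees realistic patches.
* Counts: `NB(mean = depth_s × rel_{g,class}, size theta = 2)`; per-spot
  depths log-normal (median 5000, log-sd 0.35). theta = 2 gives the strong
  overdispersion typical of spot-resolution data.
* Genes: named marker sets (hepatocyte 30, ECM 30, mesenchyme 20, lipid 44,
  cytoskeleton 89, background 50; the lipid/cytoskeleton sizes match the two
  endpoint gene sets of the motivating design, with representative endpoint
  genes PON1 and FLNA as their first members). Marker genes are elevated
  4-fold in their home compartment; hepatocyte-program genes get an
  intermediate √4 boost in "other" spots (mixed tissue), making the niche
  the clear low-hepatocyte extreme. Background probes sit ~20× below the
  median gene. 5% of unannotated genes are held off the measurement panel.
* Spots are exchangeable given class and sample — no extra within-sample
  correlation is planted — mirroring reference data in which within-patient
  spot profiles correlated no more strongly than between-patient ones.

### Bulk cohort

28 stable / 15 progressor / 15 regressor subjects; NB counts with
`theta = 8`, depths log-normal (median 2×10⁶). Planted signed log2
fold changes per gene set (progressor `+d`, regressor `−d`): lipid −0.42,
cytoskeleton +1.5, matching the endpoint effect sizes of the motivating
cohort. ECM/mesenchyme genes additionally scale 0.2 log2 per baseline
fibrosis stage — a deliberate confounder the candidate screen must absorb
with its stage covariate. Covariates: fibrosis stage F1–F4
(p = .30/.35/.25/.10) and NAS ~ clipped Poisson(4).

### ROI assembly

ROI diameter maps to aggregated spot count by the quadratic area relation
`k = round((d/55)²)`: 80 → 2, 110 → 4, 165 → 9. ROIs are grid-adjacent
patches grown from a random seed spot within one sample's class pool
(falling back to the k nearest class spots when a patch cannot grow), drawn
with replacement across ROIs, and randomly partitioned into synthetic
patients with a fixed number of ROIs each. Genes are restricted to the panel
plus background probes plus the endpoint gene. Dropout removes a uniform
random ROI subset, rejection-sampled so no patient loses all ROIs.

## 4. Discovery stages

* **Normalization**: `log2(count / sf + 1)`. `sf` defaults to strict
  median-of-ratios (error if no gene is expressed everywhere — the right
  contract for bulk); the `poscounts` variant (geometric means over positive
  counts, per-column median over positive ratios) serves sparse spot
  matrices. This is a declared stand-in for variance-stabilizing transforms;
  it preserves the log-scale depth-corrected semantics the screen and scores
  need.
* **Candidate screen**: per-gene OLS of normalized expression on outcome
  group (two treatment contrasts vs stable) plus fibrosis stage; selected =
  opposite-direction progressor/regressor effects, both p < 0.05.
* **Summary score**: mean normalized expression of a gene set after one
  filter-and-update pass dropping members correlating < 0.1 with the initial
  mean (constant members are retained — no evidence against them).
* **Segmentation**: per sample, niche = ECM score ≥ 85th percentile ∧
  hepatocyte score ≤ 15th; hepatocyte = hepatocyte score ≥ 20th ∧ ECM ≤
  80th ∧ not niche; ties inclusive. On default synthetic tissue this
  recovers > 95% of true niche spots; hepatocyte recall is structurally
  ~0.87 because the ≥ 20th-percentile cut removes a slice of genuine
  hepatocytes when they are 65% of spots.

## 5. Power engine

Per grid condition (endpoint × patients × ROIs × diameter × spike), each
repeat derives its seed as `sha256(master_seed, condition_key, rep)` — cells
are independent and grid order is irrelevant — then assembles a two-group
ROI dataset (control pool vs spiked pool), computes TMM offsets on panel
genes, and tests the endpoint gene. Power = rejections / converged repeats
(a config switch counts non-converged as failures), with convergence rate
reported alongside; log2FC is summarized as median and IQR. α defaults to
0.025 (0.05 split over two endpoints; `alpha_adjust` also produces the
transcriptome-wide 1.25e−5 variant).

## 6. Problem sizes and test budget

The default demo/pipeline size (3 samples, 24×24 grids, 300 genes) and the
test fixture sizes are the package's own choices, picked so the full suite
(including the 1000-repeat type-I check and 200-repeat monotonicity cells)
runs in well under half an hour on one core.

## 7. Limitations

* The normalization is a simple log transform, not rlog/VST; adequate for
  screening and scores, not for variance-sensitive downstream methods.
* The Wald GLMM is mildly anticonservative at small patient counts
  (measured 0.034 at nominal 0.025 under the default null); the LRT and the
  plugin interface exist for stricter alternatives.
* ROIs are resampled with replacement from a fixed spot population; no
  patient-level biological effect is planted beyond the model's random
  intercept, so between-patient variance in the synthetic power runs stems
  from sampling alone.
* Only the negative-binomial family is implemented; zero-inflation and
  probe-level background models (e.g. GeoDiff-style) are out of scope and
  reachable only through the plugin hook.
* No vendor GeoMx DCC/PKC ingestion; I/O covers MTX triplets and CSV.
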