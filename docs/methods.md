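# Methods

## Scope

`marginsig` re-implements, as reusable and tested code, the validation
analysis of a fixed 4-gene recurrence signature assayed in histologically
normal OSCC resection margins: count normalization, risk scoring and
aggregation, threshold stratification, censored-survival performance
metrics, and the Monte-Carlo margin-subsampling robustness analysis. It
does not refit the signature coefficients, model margin geometry, perform
pathway analysis, or correct batch effects.

## Normalization

The chain runs in the fixed nCounter order:

1. **Positive controls.** Per-sample factor = (arithmetic mean over samples
   of the per-sample geometric means of the positive probes) / (that
   sample's geometric mean). All of a sample's counts are multiplied by its
   factor. This removes lane-wise technical scale. Note the arithmetic mean
   of such factors is ≥ 1 (AM–HM inequality), equal to 1 only when all
   samples agree; it is close to 1 at realistic lane variation.
2. **Background.** Per-sample level `b` from the negative probes — mean
   (default), mean + 2·SD (sample SD), or max — subtracted from every
   non-negative-class probe and floored at 0. The default is declared, not
   inferred: the source analysis does not state which variant it used.
3. **Housekeeping.** Same geometric-mean construction over GAPDH and RPS18
   (the `housekeeping.geo.mean` convention), applied to endogenous and
   housekeeping rows; corrects RNA-content differences.
4. **log2(x + 1)**, then per-gene **z-scores** across all retained samples
   pooled (sample SD, n−1). Log base and pseudocount are package choices;
   per-batch z-scoring exists as an option but is off by default, since the
   two assay batches are normalized by their own controls.

Constant genes z-score to an all-zero row with a warning rather than an
error, keeping degenerate fixtures runnable. The
`NanoStringNormalizer` transformer learns the cohort reference levels
(mean positive/housekeeping geometric means, per-gene log mean/SD) in
`fit`, so `transform` maps held-out samples onto the training scale;
`fit_transform` on one cohort reproduces the standard pooled analysis.

A useful identity for testing: multiplying one sample's counts by `c`
rescales the whole cohort by a single common constant (the reference mean
moves too); per-gene z-scores are exactly invariant when the pseudocount
is 0 and negatives are 0, and invariant to ~1e-3 otherwise at realistic
count depths.

## Risk model

Margin risk is the fixed linear combination with coefficients
0.25/0.63/0.45/0.34 on the z-scores of MMP1/COL4A1/P4HA2/THBS2. Patient
risk takes the per-gene maximum over the patient's margins *first*, then
the linear combination. This differs from the maximum of per-margin risks
(e.g. two margins each carrying one elevated gene give 0.88 rather than
0.63); with all-positive coefficients it is monotone — adding a margin
never lowers patient risk. The max-of-risks alternative is exposed as an
option. Whether the maximum is taken on z-scores or on pre-z normalized
values picks the same margin per gene (the z-transform is monotone); we
use z-scores.

Stratification thresholds are linearly interpolated quantiles (the common
statistical-software convention; the 70th percentile of 1..10 is 7.3), and
the high-risk label needs risk **strictly** above the threshold, so ties
fall low — deterministic and conservative. The threshold optimizer scans
percentiles 10–90 in steps of 5 (the source analysis reports only the
winning 70th), picks the smallest log-rank p, breaks ties toward 50, and
returns the full candidate table. Optimizing the cut on the same data
inflates significance; the acceptance suite measures this inflation on
null cohorts rather than pretending the optimized p is calibrated.

## Survival statistics

All metrics are implemented directly (lifelines serves only as an
independent cross-check in the tests):

- **Kaplan-Meier** product-limit with Greenwood variance; 95% CI on the
  log-survival scale, `S·exp(±1.96·se(log S))`, clipped to [0, 1]
  (plain Greenwood is an option).
- **Log-rank** with hypergeometric mean/variance at each distinct event
  time (ties handled there), supporting k > 2 groups through a generalized
  inverse of the covariance block; p from χ² with k−1 df.
- **Hazard ratio** from the log-rank table, (O_hi/E_hi)/(O_lo/E_lo),
  flagged `inf`/`0` when a group observed no events. A Cox
  partial-likelihood fit is a test-time cross-check only — the validation
  analysis this mirrors reports log-rank-based HRs.
- **Harrell's C** over comparable pairs (the shorter observed time must
  carry an event; equal times count only event-vs-censored; risk ties
  score 1/2).
- **ROC/AUC** with AUC via the Mann-Whitney rank identity (ties 1/2);
  accuracy/sensitivity/specificity at a supplied threshold with
  "predicted recurrent" = risk strictly above it.
- **Welch's t** (two-sided) for margin-level risks of recurrent vs
  recurrence-free patients; degenerate zero-variance cases are flagged
  explicitly.
- **Spearman randomization test** for risk vs age:
  p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1), default 10,000 seeded
  permutations.
- **Covariate prognosis**: per covariate, drop missing values (report N),
  dichotomize continuous covariates at the median, log-rank across levels,
  O/E hazard ratio only for two-level covariates.

Recurrence-free survival time is time-to-recurrence for events and
follow-up time for censored patients — the standard composite.

## Monte-Carlo subsampling

Normalization and z-scores are computed once on the full data (the assay
was run once); only the per-patient aggregation is resampled. Each
replicate draws k margins per patient uniformly without replacement
(patients with fewer than k margins are omitted, never padded),
recomputes patient risks, re-applies the threshold rule **to that
replicate's risk distribution** (the percentile is a rule, not a frozen
cut), and records HR, log-rank p, concordance and AUC. Replicates with an
empty stratum or undefined HR are stored as missing, not redrawn
(redrawing would bias the distribution), and counted in the summaries.
Per-replicate RNG streams are spawned deterministically from one seed, so
results are bit-reproducible and order-independent. Summaries are
min / 2.5th / median / 97.5th / max with linear-interpolation quantiles.

## Synthetic cohorts

The generator emulates the validation cohort's stated design: 62 patients;
margins per patient from a Poisson truncated to [1, 8] with its rate
solved so the truncated mean is 4; recurrence Bernoulli(0.55);
for each recurrent patient a Binomial(m, 0.5)-conditioned-≥1 subset of
margins carries a 1.5 log2-fold up-regulation of the four signature genes
(field-cancerization heterogeneity); event times log-normal with median
10.5 months and log-SD 0.9 (spanning ≈ 2–90 months, matching a cohort
whose recurrences ranged 2.9–86.3 months); censoring times log-normal
with median 63 months and log-SD 0.55. Counts are negative-binomial
(variance μ + αμ², α = 0.1) around gene baselines drawn log-uniformly in
[50, 5000], multiplied by a log-normal lane factor (log-SD 0.2) applied
to every probe of a sample; positive controls follow the standard
titration (128 … 0.125 fM at 200 counts/fM) with **Poisson** noise —
spike-ins carry counting noise only, and the positive-control recovery
property (factor vs inverse lane factor, Spearman ρ > 0.9) requires
near-noiseless positives; Poisson background with mean 10 (scaled by the
lane factor) is added to every probe and constitutes the negative
controls. Two batch labels in the 125:152 proportion are assigned but no
batch effect is simulated unless the stress-test `batch_shift` option is
set. Housekeeping baselines are constant across samples by construction,
so their counts are independent of recurrence.

What the generator does **not** emulate — hence what a green test does not
establish: per-patient baseline expression variability beyond NB
dispersion, FFPE degradation, spatial structure among margins, covariate–
outcome associations (age, sex, smoking are simulated independent of
recurrence), or informative censoring. With α = 0.1 the simulated signal
is stronger than the real cohort's (full-data AUC ≈ 0.95–0.99 versus the
published ≈ 0.7 regime): one consequence, measured and documented rather
than tuned away, is that the Monte-Carlo median hazard ratio saturates —
it rises clearly from k = 1 to k ≥ 2 but the k = 2 → 3 ordering sits
within resampling noise (±0.1–0.2 on a median of ≈ 6), while concordance
and AUC stay strictly monotone in k.

## Numerical conventions

- Quantiles: linear interpolation everywhere (thresholds, summaries).
- Geometric means on raw (pre-log) counts; factors reference the
  arithmetic mean of geometric means.
- Sample SDs use the n−1 denominator throughout.
- Seeds: every stochastic operation takes an explicit seed; derived
  per-replicate streams use `SeedSequence.spawn`, and identical seeds give
  bit-identical outputs.
- Errors name the offending sample/probe/patient; degenerate-but-valid
  inputs (constant genes, empty strata in a replicate) degrade gracefully
  with flags instead of aborting a whole run.

## Known limitations

- The O/E-ratio hazard ratio is a crude estimator; it tracks the Cox
  partial-likelihood HR well at moderate effects (tested) but is unstable
  when a stratum has very few events (flagged inf/0).
- Optimized-threshold p-values are not calibrated (measured inflation on
  null cohorts; see the acceptance suite).
- The asymptotic log-rank p is anti-conservative at very small n; the
  tests bound its disagreement with a permutation reference at n = 20.
- GEO-accession ingestion for the original cohort is out of scope; the
  readers accept the documented TSV/CSV layouts only.
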