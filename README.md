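# marginsig

Validation pipeline for a 4-gene prognostic signature (**MMP1, COL4A1,
P4HA2, THBS2**) measured in *histologically normal* surgical resection
margins of oral squamous cell carcinoma (OSCC). Even margins declared
tumor-free under the microscope can carry molecular field-cancerization
changes that drive local recurrence; this package implements the full
analysis used to test whether the signature separates patients who will
recur from those who will not.

It is aimed at translational researchers validating margin-based expression
biomarkers on NanoString nCounter count data (or anything shaped like it),
and at methodologists studying how many margin samples per patient such a
signature needs.

## The model

Each margin sample yields probe counts that are normalized in the fixed
nCounter order — positive-control scaling, negative-control background
subtraction, housekeeping (GAPDH, RPS18) content scaling, `log2(x+1)`,
per-gene z-scores across samples. A margin's recurrence risk is a fixed
linear score

```
risk = 0.25·z(MMP1) + 0.63·z(COL4A1) + 0.45·z(P4HA2) + 0.34·z(THBS2)
```

A patient's risk takes the **per-gene maximum across all of their margins**
first, then applies the same linear combination — because the expression
changes spread heterogeneously across margins, the most aberrant value per
gene is the informative one. Patients are stratified at the median (or an
optimized percentile) of the risk distribution and evaluated with
censored-survival metrics: Kaplan-Meier curves with Greenwood/log-scale
95% CIs, the log-rank test, a hazard ratio from the log-rank
observed/expected table, HR = (O_hi/E_hi)/(O_lo/E_lo), Harrell's
concordance index and ROC/AUC. A Monte-Carlo analysis re-estimates all
metrics when only *k* randomly chosen margins per patient are available
(patients with fewer than *k* margins are omitted), summarized by
min / 2.5% / median / 97.5% / max over the replicates.

A synthetic-cohort generator with known ground truth (negative-binomial
counts, lane-wise technical factors, Poisson background, censored
recurrence-free survival) stands in for the study data, so every stage is
testable offline. See `docs/methods.md` for the generative model and its
limits.

## Worked example

```
$ marginsig simulate --n-patients 62 --seed 42 --out demo
wrote 40 probes x 257 margins for 62 patients to demo

$ marginsig validate --counts demo/counts.tsv --clinical demo/clinical.csv \
      --out demo/results --n-reps 1000 --seed 42
N=62 patients, 257 margins | C-index 0.81, AUC 0.99 | median-threshold HR 21.58 (p=1.4e-14) | optimized (50th pct) HR 21.58 (p=1.4e-14)

$ marginsig subsample demo/counts.tsv demo/clinical.csv \
      --k 1 --k 2 --k 3 --n-reps 1000 --seed 42 --out demo/sub.json
k=1: N=62, median HR 3.74, CI 0.66, AUC 0.76
k=2: N=59, median HR 5.08, CI 0.72, AUC 0.86
k=3: N=49, median HR 5.48, CI 0.75, AUC 0.89
```

Reading the numbers: on this simulated strong-effect cohort the patient-level
score orders recurrence-free survival well (concordance 0.81), classifies
recurrence almost perfectly (AUC 0.99), and the high-risk group recurs at
~22× the rate of the low-risk group at the median cut. With only one margin
per patient the median hazard ratio over 1000 resamples drops to 3.7 and
AUC to 0.76; performance recovers as two and three margins are used —
the qualitative reason multiple margins per patient should be assayed.
`N` drops with *k* because patients contributing fewer than *k* margins
are excluded. `demo/results/` holds the re-readable TSV/JSON bundle
(risks, stratification, KM curves, ROC points, per-rep subsampling
metrics, provenance).

The same pipeline is callable as a library — `simulate_cohort`,
`NanoStringNormalizer` (a scikit-learn transformer), `SignatureModel`,
`RiskStratifier`, `ThresholdOptimizer`, the `survival` metrics and
`monte_carlo` — see the docstrings.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole validation analysis from scratch on the default
synthetic cohort — generation, normalization, margin- and patient-level
scoring, median- and optimized-threshold survival analysis, and the
k = 1/2/3 Monte-Carlo subsampling — printing the headline metrics and
writing the JSON report to `--out`. All randomness derives from `--seed`.
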