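"""End-to-end validation analysis: normalize, score, stratify, evaluate.

``run_validation`` chains every stage the validation study reports:
normalization to z-scores, per-margin risks and the recurrent-vs-
recurrence-free Welch comparison, per-patient risks via the per-gene max
across margins, concordance index, ROC/AUC at the median threshold,
median- and optimized-threshold stratification with log-rank HR and
Kaplan-Meier curves, the risk-age Spearman randomization test, an optional
covariate prognosis table, and Monte-Carlo margin subsampling for each k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import NormalizedMatrix, ProbeCountMatrix
from .io import check_consistency, read_clinical, read_counts, write_json
from .normalize import normalize_pipeline
from .risk import (
    DEFAULT_PERCENTILE_GRID,
    SignatureModel,
    Stratification,
    optimize_threshold,
    stratify,
)
from .subsampling import monte_carlo
from .survival import (
    concordance_index,
    hazard_ratio_from_logrank,
    km_estimate,
    logrank,
    roc_auc,
    spearman_permutation,
    covariate_prognosis,
    welch_t,
)

log = logging.getLogger("marginsig")


@dataclass
class AnalysisConfig:
    counts: str
    clinical: str
    out_dir: str = "results"
    background_method: str = "mean"
    hk_genes: tuple[str, ...] = ("GAPDH", "RPS18")
    optimized_percentile: float | None = None  # None -> grid search
    percentile_grid: tuple[float, ...] = DEFAULT_PERCENTILE_GRID
    subsample_k: tuple[int, ...] = (1, 2, 3)
    n_reps: int = 10_000
    seed: int = 0
    covariates: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("hk_genes", "percentile_grid", "subsample_k"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "clinical": self.clinical,
            "out_dir": self.out_dir,
            "background_method": self.background_method,
            "hk_genes": list(self.hk_genes),
            "optimized_percentile": self.optimized_percentile,
            "percentile_grid": list(self.percentile_grid),
            "subsample_k": list(self.subsample_k),
            "n_reps": self.n_reps,
            "seed": self.seed,
            "covariates": dict(self.covariates),
        }


def _group_metrics(groups: pd.Series, outcomes: pd.DataFrame) -> dict:
    times = outcomes.loc[groups.index, "time_months"].to_numpy(dtype=float)
    events = outcomes.loc[groups.index, "event"].to_numpy(dtype=int)
    res = logrank(groups.to_numpy(), times, events)
    hr = hazard_ratio_from_logrank(res.observed, res.expected, "high")
    return {
        "HR": hr,
        "chi_square": res.chi_square,
        "p_value": res.p_value,
        "observed": res.observed.to_dict(),
        "expected": res.expected.to_dict(),
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
    }


def _km_frames(groups: pd.Series, outcomes: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for g in ("low", "high"):
        ids = groups.index[groups == g]
        if len(ids) == 0:
            continue
        curve = km_estimate(outcomes.loc[ids, "time_months"],
                            outcomes.loc[ids, "event"])
        frame = curve.to_frame()
        frame.insert(0, "group", g)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def analyze_cohort(
    counts: ProbeCountMatrix,
    annotation: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full validation analysis on in-memory inputs.

    Returns a result bundle (plain dict, JSON-serializable except for the
    embedded DataFrames under 'tables').
    """
    config = config or AnalysisConfig(counts="<memory>", clinical="<memory>")
    check_consistency(counts, annotation)
    model = SignatureModel().fit()

    log.info("normalizing %d probes x %d samples", *counts.counts.shape)
    normalized: NormalizedMatrix = normalize_pipeline(
        counts, background_method=config.background_method,
        hk_genes=tuple(config.hk_genes),
    )

    margin_risks = model.sample_risks(normalized)
    recurrent_patients = outcomes.index[outcomes["event"] == 1]
    margin_rec = annotation.loc[margin_risks.index, "patient_id"].isin(recurrent_patients)
    t_stat, t_df, t_p = welch_t(margin_risks[margin_rec.to_numpy()],
                                margin_risks[~margin_rec.to_numpy()])

    patient_risks = model.patient_risks(normalized, annotation)
    patient_risks = patient_risks.loc[outcomes.index]
    times = outcomes["time_months"].to_numpy(dtype=float)
    events = outcomes["event"].to_numpy(dtype=int)

    cindex = concordance_index(patient_risks.to_numpy(), times, events)
    median_strat: Stratification = stratify(patient_risks, rule="median")
    roc = roc_auc(patient_risks.to_numpy(), events, threshold=median_strat.threshold)

    median_metrics = _group_metrics(median_strat.groups, outcomes)

    if config.optimized_percentile is not None:
        opt_q = float(config.optimized_percentile)
        opt_strat = stratify(patient_risks, rule="percentile", q=opt_q)
        opt_table = None
    else:
        opt_q, opt_strat, opt_table = optimize_threshold(
            patient_risks, outcomes, grid=tuple(config.percentile_grid)
        )
    opt_metrics = _group_metrics(opt_strat.groups, outcomes)

    rho, rho_p = (np.nan, np.nan)
    if "age" in outcomes.columns and outcomes["age"].notna().all():
        rho, rho_p = spearman_permutation(
            patient_risks.to_numpy(), outcomes["age"].to_numpy(dtype=float),
            seed=config.seed,
        )

    covar_table = None
    if config.covariates:
        covar_table = covariate_prognosis(outcomes, config.covariates)

    subsampling = {}
    sub_tables = {}
    for k in config.subsample_k:
        log.info("Monte-Carlo subsampling k=%d, %d reps", k, config.n_reps)
        result = monte_carlo(
            normalized, annotation, outcomes, model=model, k=k,
            n_reps=config.n_reps, threshold_q=70.0, seed=config.seed + k,
        )
        subsampling[str(k)] = result.to_dict()
        sub_tables[k] = result.per_rep

    bundle = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        },
        "n_patients": int(len(outcomes)),
        "n_margins": int(len(margin_risks)),
        "welch_margin_risks": {"t": t_stat, "df": t_df, "p_value": t_p},
        "concordance_index": cindex,
        "roc": {
            "AUC": roc.auc,
            "accuracy": roc.accuracy,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "threshold": roc.threshold,
        },
        "median_threshold": {"threshold": median_strat.threshold, **median_metrics},
        "optimized_threshold": {
            "percentile": opt_q,
            "threshold": opt_strat.threshold,
            **opt_metrics,
        },
        "age_correlation": {"rho": rho, "p_value": rho_p},
        "subsampling": subsampling,
        "tables": {
            "margin_risks": margin_risks,
            "patient_risks": patient_risks,
            "median_groups": median_strat.groups,
            "optimized_groups": opt_strat.groups,
            "km_median": _km_frames(median_strat.groups, outcomes),
            "km_optimized": _km_frames(opt_strat.groups, outcomes),
            "optimization": opt_table,
            "covariates": covar_table,
            "normalization_factors": pd.DataFrame({
                "positive_factor": normalized.positive_factors,
                "background": normalized.background,
                "housekeeping_factor": normalized.housekeeping_factors,
            }),
            "subsampling_reps": sub_tables,
            "roc_points": pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr,
                                        "threshold": roc.thresholds}),
        },
    }
    return bundle


def run_validation(config: AnalysisConfig) -> dict:
    """Load inputs per config, run the analysis and write the result bundle."""
    counts = read_counts(config.counts)
    annotation, outcomes = read_clinical(config.clinical)
    bundle = analyze_cohort(counts, annotation, outcomes, config)
    write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = bundle["tables"]
    tables["margin_risks"].rename_axis("sample_id").to_csv(
        out / "margin_risks.tsv", sep="\t", header=["risk"])
    tables["patient_risks"].rename_axis("patient_id").to_csv(
        out / "patient_risks.tsv", sep="\t", header=["risk"])
    strat = pd.DataFrame({
        "risk": tables["patient_risks"],
        "median_group": tables["median_groups"],
        "optimized_group": tables["optimized_groups"],
    })
    strat.rename_axis("patient_id").to_csv(out / "stratification.tsv", sep="\t")
    tables["km_median"].to_csv(out / "km_median.tsv", sep="\t", index=False)
    tables["km_optimized"].to_csv(out / "km_optimized.tsv", sep="\t", index=False)
    tables["normalization_factors"].rename_axis("sample_id").to_csv(
        out / "normalization_factors.tsv", sep="\t")
    tables["roc_points"].to_csv(out / "roc_points.tsv", sep="\t", index=False)
    if tables["optimization"] is not None:
        tables["optimization"].to_csv(out / "threshold_optimization.tsv",
                                      sep="\t", index=False)
    if tables["covariates"] is not None:
        tables["covariates"].to_csv(out / "covariate_prognosis.tsv", sep="\t")
    for k, per_rep in tables["subsampling_reps"].items():
        per_rep.to_csv(out / f"subsampling_k{k}_reps.tsv", sep="\t", index=False)
    slim = {key: val for key, val in bundle.items() if key != "tables"}
    write_json(slim, out / "results.json")
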