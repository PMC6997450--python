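"""Monte-Carlo margin subsampling: signature performance with k margins.

Normalization and z-scoring are computed once on the full data; each rep
draws k margins per patient uniformly without replacement (patients with
fewer than k margins are omitted, not padded), re-aggregates patient risks
via the per-gene maximum over the selected margins, re-applies the
threshold rule to that rep's risk distribution and records HR, log-rank p,
Harrell's C and AUC. Reps where a stratum is empty record missing HR/p
rather than crashing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import NormalizedMatrix
from .risk import RiskStratifier, SignatureModel
from .survival import concordance_index, hazard_ratio_from_logrank, logrank, roc_auc

METRICS = ("HR", "p_value", "concordance", "AUC")


def five_number_summary(values) -> dict[str, float]:
    """Minimum, 2.5th percentile, median, 97.5th percentile, maximum.

    Quantiles use linear interpolation; missing (NaN) reps are excluded.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("all values are missing")
    q = np.percentile(finite, [2.5, 50.0, 97.5])
    return {
        "min": float(finite.min()),
        "p2.5": float(q[0]),
        "median": float(q[1]),
        "p97.5": float(q[2]),
        "max": float(finite.max()),
        "n_missing": int(values.size - finite.size),
    }


summarize = five_number_summary


@dataclass
class SubsamplingResult:
    """Per-rep metric distributions and their five-number summaries."""

    k: int
    n_reps: int
    n_patients: int  # retained (>= k margins)
    per_rep: pd.DataFrame  # columns = METRICS, one row per rep
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0
    threshold_rule: str = "percentile(70)"

    def __post_init__(self) -> None:
        if len(self.per_rep) != self.n_reps:
            raise ValueError("per-rep table length does not match n_reps")
        if not self.summary:
            self.summary = {}
            for m in METRICS:
                try:
                    self.summary[m] = five_number_summary(self.per_rep[m])
                except ValueError:  # every rep missing for this metric
                    self.summary[m] = {k: float("nan") for k in
                                       ("min", "p2.5", "median", "p97.5", "max")}
                    self.summary[m]["n_missing"] = int(len(self.per_rep))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_reps": self.n_reps,
            "n_patients": self.n_patients,
            "seed": self.seed,
            "threshold_rule": self.threshold_rule,
            "summary": self.summary,
        }


def subsample_patients(
    annotation: pd.DataFrame, k: int, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Choose k margins per patient uniformly without replacement.

    Patients with fewer than k margins are excluded from the returned map.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: dict[str, list[str]] = {}
    for pid, rows in annotation.groupby("patient_id", sort=True):
        ids = rows.index.to_numpy()
        if len(ids) < k:
            continue
        selected[str(pid)] = list(rng.choice(ids, size=k, replace=False))
    return selected


def monte_carlo(
    normalized: NormalizedMatrix,
    annotation: pd.DataFrame,
    outcomes: pd.DataFrame,
    model: SignatureModel | None = None,
    k: int = 1,
    n_reps: int = 10_000,
    threshold_rule: str = "percentile",
    threshold_q: float = 70.0,
    seed: int = 0,
) -> SubsamplingResult:
    """Repeat the per-patient risk analysis on k randomly chosen margins.

    Each rep has its own deterministic random stream spawned from ``seed``,
    so results are reproducible and independent of rep execution order.
    """
    model = model or SignatureModel()
    _, coef = model._validated()
    values = normalized if hasattr(normalized, "loc") else normalized.values
    block = model._signature_block(values)

    # per-patient gene sub-blocks for fast per-rep aggregation
    patients: list[str] = []
    blocks: list[np.ndarray] = []
    counts: list[int] = []
    for pid, rows in annotation.groupby("patient_id", sort=True):
        ids = [s for s in rows.index if s in block.columns]
        if len(ids) != len(rows):
            missing = set(rows.index) - set(ids)
            raise ValueError(f"annotated samples missing from matrix: {sorted(missing)}")
        if len(ids) < k:
            continue
        patients.append(str(pid))
        blocks.append(block[ids].to_numpy(dtype=float))
        counts.append(len(ids))
    if not patients:
        raise ValueError(f"no patient has >= {k} margins")

    times = outcomes.loc[patients, "time_months"].to_numpy(dtype=float)
    events = outcomes.loc[patients, "event"].to_numpy(dtype=int)

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    records = np.full((n_reps, len(METRICS)), np.nan)
    for rep in range(n_reps):
        rng = np.random.default_rng(streams[rep])
        risks = np.empty(len(patients))
        for i, (sub, m) in enumerate(zip(blocks, counts)):
            idx = rng.choice(m, size=k, replace=False)
            risks[i] = coef @ sub[:, idx].max(axis=1)
        risk_series = pd.Series(risks, index=patients)
        strat = RiskStratifier(rule=threshold_rule, q=threshold_q).fit_predict(risk_series)
        groups = strat.to_numpy()
        c = concordance_index(risks, times, events)
        auc = roc_auc(risks, events, threshold=np.median(risks)).auc
        if (groups == "high").any() and (groups == "low").any():
            res = logrank(groups, times, events)
            hr = hazard_ratio_from_logrank(res.observed, res.expected, "high")
            records[rep] = (hr, res.p_value, c, auc)
        else:
            records[rep, 2] = c
            records[rep, 3] = auc
    per_rep = pd.DataFrame(records, columns=list(METRICS))
    rule_name = threshold_rule if threshold_rule != "percentile" else f"percentile({threshold_q:g})"
    return SubsamplingResult(
        k=k,
        n_reps=n_reps,
        n_patients=len(patients),
        per_rep=per_rep,
        seed=seed,
        threshold_rule=rule_name,
    )
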