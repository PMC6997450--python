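"""Synthetic NanoString-style margin cohorts with known ground truth.

The generator emulates the structure of a surgical-margin validation cohort:
~62 patients contributing 1-8 histologically normal margins each (average 4),
~55% of patients with local recurrence, recurrence-linked up-regulation of
the four signature genes confined to a random subset of each recurrent
patient's margins (field-cancerization heterogeneity), stable housekeeping
genes, lane-wise technical scale factors that positive-control normalization
must remove, Poisson background that negative-control correction must
remove, and censored recurrence-free survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    HOUSEKEEPING_GENES,
    ProbeCountMatrix,
    SIGNATURE_GENES,
)

# Standard nCounter positive-control titration (fM).
POSITIVE_CONCENTRATIONS = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
#: Expected counts per fM of positive-control target.
POSITIVE_SCALE = 200.0

#: Log-sigma of event times; with median 10.5 months this spans roughly
#: 1-90 months, matching a cohort whose recurrences fall between 3 and 86
#: months after surgery.
EVENT_LOG_SIGMA = 0.9
CENSOR_LOG_SIGMA = 0.55

#: Relative sizes of the two assay batches (margins were run in two lanes
#: of roughly 125 and 152 samples).
BATCH_PROPORTIONS = (125, 152)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the validation-cohort design: 62 patients, 1-8
    margins each averaging 4, 55% recurrence, 1.5 log2-fold up-regulation of
    the signature genes in roughly half of each recurrent patient's margins,
    median time-to-recurrence 10.5 months and median follow-up 63 months.
    """

    n_patients: int = 62
    margins_min: int = 1
    margins_max: int = 8
    margins_mean: float = 4.0
    recurrence_rate: float = 0.55
    affected_margin_fraction: float = 0.5
    effect_size: float = 1.5
    n_endogenous_background: int = 20
    lane_scale_sd: float = 0.2
    negative_mean: float = 10.0
    dispersion: float = 0.1
    tte_median_months: float = 10.5
    followup_median_months: float = 63.0
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.margins_min < 1:
            raise ValueError("margins_min must be >= 1")
        if self.margins_max < self.margins_min:
            raise ValueError("margins_max must be >= margins_min")
        if not (self.margins_min <= self.margins_mean <= self.margins_max):
            raise ValueError("margins_mean must lie in [margins_min, margins_max]")
        for name in ("recurrence_rate", "affected_margin_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.lane_scale_sd < 0:
            raise ValueError("lane_scale_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    recurrence: dict[str, bool]
    affected_margins: dict[str, list[str]] = field(default_factory=dict)
    lane_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        for pid, margins in self.affected_margins.items():
            if self.recurrence.get(pid) and len(margins) == 0:
                raise ValueError(f"recurrent patient {pid} has no affected margin")
            if not self.recurrence.get(pid) and len(margins) > 0:
                raise ValueError(f"non-recurrent patient {pid} has affected margins")


def _truncated_poisson_lambda(lo: int, hi: int, mean: float) -> float:
    """Rate whose truncation to [lo, hi] has the requested mean."""
    if lo == hi:
        return float(lo)
    ks = np.arange(lo, hi + 1)

    def trunc_mean(lam: float) -> float:
        w = stats.poisson.pmf(ks, lam)
        return float((ks * w).sum() / w.sum())

    if math.isclose(trunc_mean(1e-8), mean, abs_tol=1e-6):
        return 1e-8
    return float(optimize.brentq(lambda lam: trunc_mean(lam) - mean, 1e-8, 100.0))


def _sample_truncated_poisson(rng: np.random.Generator, lam: float,
                              lo: int, hi: int, size: int) -> np.ndarray:
    ks = np.arange(lo, hi + 1)
    w = stats.poisson.pmf(ks, lam)
    return rng.choice(ks, size=size, p=w / w.sum())


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha * mu^2."""
    n = 1.0 / alpha
    p = n / (n + np.asarray(mean, dtype=float))
    return rng.negative_binomial(n, p)


def simulate_cohort(
    config: SimConfig,
) -> tuple[ProbeCountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns
    -------
    counts : ProbeCountMatrix
        Signature + background endogenous genes, GAPDH/RPS18 housekeeping,
        6 graded positive controls and 8 negative controls; integer counts
        drawn negative-binomially around lane_factor * baseline * fold plus
        Poisson background.
    annotation : DataFrame indexed by sample_id with ``patient_id``/``batch``.
    outcomes : DataFrame indexed by patient_id with ``event``, ``time_months``,
        ``age``, and binary/categorical covariates.
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)

    patient_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    lam = _truncated_poisson_lambda(config.margins_min, config.margins_max,
                                    config.margins_mean)
    n_margins = _sample_truncated_poisson(rng, lam, config.margins_min,
                                          config.margins_max, config.n_patients)

    sample_ids: list[str] = []
    sample_patient: list[str] = []
    for pid, m in zip(patient_ids, n_margins):
        for j in range(m):
            sample_ids.append(f"{pid}_M{j + 1}")
            sample_patient.append(pid)
    n_samples = len(sample_ids)

    # Recurrence status and affected margins
    recurrent = rng.random(config.n_patients) < config.recurrence_rate
    truth_rec = {pid: bool(r) for pid, r in zip(patient_ids, recurrent)}
    affected: dict[str, list[str]] = {pid: [] for pid in patient_ids}
    for pid, m, rec in zip(patient_ids, n_margins, recurrent):
        if not rec:
            continue
        # Binomial(m, fraction) conditioned on >= 1 affected margin
        while True:
            k = rng.binomial(m, config.affected_margin_fraction)
            if k >= 1:
                break
        chosen = rng.choice(m, size=k, replace=False)
        affected[pid] = sorted(f"{pid}_M{j + 1}" for j in chosen)
    affected_ids = {s for margins in affected.values() for s in margins}

    # Probe panel
    bg_genes = [f"BGD{i + 1:03d}" for i in range(config.n_endogenous_background)]
    endo_genes = list(SIGNATURE_GENES) + bg_genes
    pos_probes = [f"POS_{chr(65 + i)}" for i in range(len(POSITIVE_CONCENTRATIONS))]
    neg_probes = [f"NEG_{chr(65 + i)}" for i in range(8)]
    probes = endo_genes + list(HOUSEKEEPING_GENES) + pos_probes + neg_probes
    probe_class = pd.Series(
        ["Endogenous"] * len(endo_genes)
        + ["Housekeeping"] * len(HOUSEKEEPING_GENES)
        + ["Positive"] * len(pos_probes)
        + ["Negative"] * len(neg_probes),
        index=probes,
    )
    nominal = pd.Series(POSITIVE_CONCENTRATIONS, index=pos_probes)

    # Gene-specific baselines, log-uniform in [50, 5000]
    n_bio = len(endo_genes) + len(HOUSEKEEPING_GENES)
    baselines = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), size=n_bio))

    lane = np.exp(rng.normal(0.0, config.lane_scale_sd, size=n_samples))
    lane_factors = pd.Series(lane, index=sample_ids)

    # Batch labels proportional to the two assay runs; optional shift for
    # stress tests only (no batch effect by default).
    frac1 = BATCH_PROPORTIONS[0] / sum(BATCH_PROPORTIONS)
    n_b1 = int(round(frac1 * n_samples))
    batch = pd.Series(["B1"] * n_b1 + ["B2"] * (n_samples - n_b1), index=sample_ids)
    batch_mult = np.where(batch.to_numpy() == "B2", 2.0 ** config.batch_shift, 1.0)

    # Expected biological counts: baseline x fold-change (signature genes in
    # affected margins only), then lane factor, then Poisson background.
    fold = np.ones((n_bio, n_samples))
    affected_mask = np.array([s in affected_ids for s in sample_ids])
    for gi in range(len(SIGNATURE_GENES)):
        fold[gi, affected_mask] = 2.0 ** config.effect_size

    mu_bio = baselines[:, None] * fold * lane[None, :] * batch_mult[None, :]
    counts_bio = _nb_counts(rng, mu_bio, config.dispersion)

    # Spike-in positive controls carry counting noise only (Poisson, like
    # the negatives), not the biological overdispersion of tissue probes.
    mu_pos = (np.asarray(POSITIVE_CONCENTRATIONS)[:, None] * POSITIVE_SCALE
              * lane[None, :])
    counts_pos = rng.poisson(mu_pos)

    # Background: Poisson(lane * negative_mean) for every probe; negatives
    # are pure background.
    bg_mean = lane[None, :] * config.negative_mean
    counts_bio = counts_bio + rng.poisson(np.broadcast_to(bg_mean, counts_bio.shape))
    counts_pos = counts_pos + rng.poisson(np.broadcast_to(bg_mean, counts_pos.shape))
    counts_neg = rng.poisson(np.broadcast_to(bg_mean, (len(neg_probes), n_samples)))

    counts = pd.DataFrame(
        np.vstack([counts_bio, counts_pos, counts_neg]),
        index=probes,
        columns=sample_ids,
        dtype=np.int64,
    )

    # Censored recurrence-free survival
    tte = np.exp(rng.normal(np.log(config.tte_median_months), EVENT_LOG_SIGMA,
                            size=config.n_patients))
    fup = np.exp(rng.normal(np.log(config.followup_median_months), CENSOR_LOG_SIGMA,
                            size=config.n_patients))
    time = np.where(recurrent, tte, fup)
    event = recurrent.astype(int)

    age = np.clip(rng.normal(64.5, 11.0, size=config.n_patients), 27, 90).round(1)
    sex = rng.choice(["F", "M"], size=config.n_patients, p=[27 / 62, 35 / 62])
    smoking = rng.choice(["never", "former", "current"], size=config.n_patients,
                         p=[23 / 61, 15 / 61, 23 / 61])

    annotation = pd.DataFrame(
        {"patient_id": sample_patient, "batch": batch.to_numpy()},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    outcomes = pd.DataFrame(
        {
            "event": event,
            "time_months": time,
            "age": age,
            "sex": sex,
            "smoking": smoking,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )

    truth = GroundTruth(recurrence=truth_rec, affected_margins=affected,
                        lane_factors=lane_factors)
    matrix = ProbeCountMatrix(counts=counts, probe_class=probe_class,
                              nominal_conc=nominal, batch=batch)
    return matrix, annotation, outcomes, truth


def affected_margin_mask(truth: GroundTruth, annotation: pd.DataFrame) -> pd.Series:
    """Boolean per-sample mask, True exactly for ground-truth affected margins."""
    known = set(annotation.index)
    affected = {s for margins in truth.affected_margins.values() for s in margins}
    unknown = affected - known
    if unknown:
        raise ValueError(f"affected margins not in annotation: {sorted(unknown)}")
    return pd.Series([s in affected for s in annotation.index],
                     index=annotation.index, name="affected")
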