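"""Signature risk scoring and threshold-based patient stratification.

Risk is a fixed linear combination of the z-scored expressions of MMP1,
COL4A1, P4HA2 and THBS2 with published coefficients 0.25, 0.63, 0.45, 0.34.
A patient's risk aggregates their margins by taking the per-gene maximum
across margins first and scoring the resulting profile (not the maximum of
per-margin risks; with positive coefficients the per-gene max is never
smaller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import NormalizedMatrix, SIGNATURE_COEFFICIENTS, SIGNATURE_GENES
from .survival import logrank


class SignatureModel(BaseEstimator):
    """The fixed 4-gene linear risk model.

    Parameters
    ----------
    genes, coefficients : signature definition; defaults are the published
        4-gene signature.
    aggregation : {'max_gene', 'max_risk'}
        How a patient's margins combine: per-gene maximum then linear
        combination (default), or maximum of per-margin risks.
    """

    def __init__(
        self,
        genes: tuple[str, ...] = SIGNATURE_GENES,
        coefficients: tuple[float, ...] = SIGNATURE_COEFFICIENTS,
        aggregation: str = "max_gene",
    ) -> None:
        self.genes = genes
        self.coefficients = coefficients
        self.aggregation = aggregation

    def _validated(self) -> tuple[list[str], np.ndarray]:
        genes = list(self.genes)
        coef = np.asarray(self.coefficients, dtype=float)
        if len(genes) != len(coef):
            raise ValueError("genes and coefficients must have the same length")
        if not np.isfinite(coef).all():
            raise ValueError("coefficients must be finite")
        if self.aggregation not in ("max_gene", "max_risk"):
            raise ValueError("aggregation must be 'max_gene' or 'max_risk'")
        return genes, coef

    def fit(self, X=None, y=None) -> "SignatureModel":
        """No-op (coefficients are fixed); kept for pipeline compatibility."""
        genes, coef = self._validated()
        self.genes_ = genes
        self.coef_ = coef
        return self

    def _signature_block(self, values: pd.DataFrame) -> pd.DataFrame:
        genes, _ = self._validated()
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise ValueError(f"signature genes missing from expression matrix: {missing}")
        return values.loc[genes]

    def sample_risks(self, normalized: NormalizedMatrix | pd.DataFrame) -> pd.Series:
        """Per-margin risk: sum_g coefficient_g * z_g."""
        values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
        _, coef = self._validated()
        block = self._signature_block(values)
        return pd.Series(coef @ block.to_numpy(dtype=float),
                         index=block.columns, name="risk")

    def patient_risks(
        self,
        normalized: NormalizedMatrix | pd.DataFrame,
        annotation: pd.DataFrame,
        samples: pd.Index | None = None,
    ) -> pd.Series:
        """Per-patient risk over (optionally a subset of) their margins."""
        values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
        _, coef = self._validated()
        block = self._signature_block(values)
        if samples is not None:
            block = block[list(samples)]
        missing = block.columns.difference(annotation.index)
        if len(missing):
            raise ValueError(f"samples without annotation: {missing.tolist()}")
        patients = annotation.loc[block.columns, "patient_id"]
        out = {}
        for pid, cols in block.T.groupby(patients):
            sub = cols.T.to_numpy(dtype=float)  # genes x margins
            if sub.shape[1] == 0:
                raise ValueError(f"patient {pid} has no margins")
            if self.aggregation == "max_gene":
                out[pid] = float(coef @ sub.max(axis=1))
            else:
                out[pid] = float((coef @ sub).max())
        return pd.Series(out, name="risk").rename_axis("patient_id")


def sample_risk(z: pd.Series, model: SignatureModel | None = None) -> float:
    """Risk of a single margin from its per-gene z-scores."""
    model = model or SignatureModel()
    return float(model.sample_risks(z.to_frame("s")).iloc[0])


def patient_risk(margins: pd.DataFrame, model: SignatureModel | None = None) -> float:
    """Risk of one patient from a genes x margins z-score block."""
    model = model or SignatureModel()
    if margins.shape[1] == 0:
        raise ValueError("patient has no margins")
    ann = pd.DataFrame({"patient_id": ["p"] * margins.shape[1]}, index=margins.columns)
    return float(model.patient_risks(margins, ann).iloc[0])


@dataclass
class Stratification:
    """Two-group split of patients at a risk threshold (ties go low)."""

    threshold: float
    rule: str
    groups: pd.Series  # id -> 'low' | 'high'

    @property
    def n_high(self) -> int:
        return int((self.groups == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.groups == "low").sum())


class RiskStratifier(BaseEstimator):
    """Learn a risk threshold (median / percentile / fixed) and assign groups.

    The threshold is the linearly interpolated quantile of the fitted risks;
    a patient is 'high' iff risk > threshold (strict, so ties fall low).
    """

    def __init__(self, rule: str = "median", q: float = 50.0,
                 value: float | None = None) -> None:
        self.rule = rule
        self.q = q
        self.value = value

    def fit(self, risks: pd.Series, y=None) -> "RiskStratifier":
        risks = pd.Series(risks)
        if self.rule == "median":
            if len(risks) < 2:
                raise ValueError("need >= 2 patients to stratify")
            self.threshold_ = float(np.median(risks))
        elif self.rule == "percentile":
            if not (0.0 < self.q < 100.0):
                raise ValueError("percentile q must be in (0, 100)")
            if len(risks) < 2:
                raise ValueError("need >= 2 patients to stratify")
            self.threshold_ = float(np.percentile(risks, self.q))
        elif self.rule == "fixed":
            if self.value is None:
                raise ValueError("fixed rule requires a threshold value")
            self.threshold_ = float(self.value)
        else:
            raise ValueError(f"unknown stratification rule {self.rule!r}")
        return self

    def predict(self, risks: pd.Series) -> pd.Series:
        if not hasattr(self, "threshold_"):
            raise ValueError("RiskStratifier is not fitted")
        risks = pd.Series(risks)
        return pd.Series(np.where(risks > self.threshold_, "high", "low"),
                         index=risks.index, name="group")

    def fit_predict(self, risks: pd.Series) -> pd.Series:
        return self.fit(risks).predict(risks)


def stratify(risks: pd.Series, rule: str = "median", q: float = 50.0,
             value: float | None = None) -> Stratification:
    """Threshold patient risks into low/high groups."""
    strat = RiskStratifier(rule=rule, q=q, value=value).fit(risks)
    name = rule if rule != "percentile" else f"percentile({q:g})"
    return Stratification(threshold=strat.threshold_, rule=name,
                          groups=strat.predict(risks))


DEFAULT_PERCENTILE_GRID = tuple(range(10, 95, 5))


class ThresholdOptimizer(BaseEstimator):
    """Pick the percentile cut that minimizes the log-rank p-value.

    Evaluates each candidate percentile of the risk distribution, stratifies
    strictly above the cut and computes the two-group log-rank p. Candidates
    leaving a group empty are skipped with a warning. Ties on p break toward
    the candidate nearest the median (then the smaller percentile).
    """

    def __init__(self, grid: tuple[float, ...] = DEFAULT_PERCENTILE_GRID) -> None:
        self.grid = grid

    def fit(self, risks: pd.Series, outcomes: pd.DataFrame) -> "ThresholdOptimizer":
        grid = list(self.grid)
        if not grid:
            raise ValueError("candidate grid is empty")
        risks = pd.Series(risks)
        times = outcomes.loc[risks.index, "time_months"].to_numpy(dtype=float)
        events = outcomes.loc[risks.index, "event"].to_numpy(dtype=int)
        rows = []
        for q in grid:
            s = stratify(risks, rule="percentile", q=q)
            if s.n_high == 0 or s.n_low == 0:
                warnings.warn(f"candidate percentile {q} leaves an empty group; skipped",
                              stacklevel=2)
                rows.append((q, s.threshold, np.nan, s.n_high))
                continue
            res = logrank(s.groups.to_numpy(), times, events)
            rows.append((q, s.threshold, res.p_value, s.n_high))
        table = pd.DataFrame(rows, columns=["percentile", "threshold", "p_value", "n_high"])
        if table["p_value"].isna().all():
            raise ValueError("every candidate percentile left an empty group")
        valid = table.dropna(subset=["p_value"])
        pmin = valid["p_value"].min()
        ties = valid[valid["p_value"] == pmin].copy()
        ties["dist50"] = (ties["percentile"] - 50.0).abs()
        best = ties.sort_values(["dist50", "percentile"]).iloc[0]
        self.table_ = table
        self.percentile_ = float(best["percentile"])
        self.p_value_ = float(best["p_value"])
        self.stratification_ = stratify(risks, rule="percentile", q=self.percentile_)
        return self


def optimize_threshold(
    risks: pd.Series,
    outcomes: pd.DataFrame,
    grid: tuple[float, ...] = DEFAULT_PERCENTILE_GRID,
) -> tuple[float, Stratification, pd.DataFrame]:
    """Grid-search the stratification percentile for minimal log-rank p."""
    opt = ThresholdOptimizer(grid=grid).fit(risks, outcomes)
    return opt.percentile_, opt.stratification_, opt.table_
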