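"""Censored-survival and classification metrics.

Implements the estimators the validation analysis reports: Kaplan-Meier
with Greenwood variance and log-scale 95% CIs, the k-group log-rank test
with hypergeometric variance at each event time, a hazard ratio derived
from the log-rank observed/expected table (HR = (O1/E1)/(O0/E0)), Harrell's
concordance index, ROC/AUC via the Mann-Whitney identity, Welch's t-test, a
Spearman randomization test, and a per-covariate prognosis table.

The recurrence-free survival time of a patient is their time to recurrence
when the event occurred and their follow-up (censoring) time otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate on the distinct event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
        })


def km_estimate(times, events, alpha: float = 0.05, ci: str = "log") -> KMCurve:
    """Kaplan-Meier estimator with Greenwood variance and 95% CI.

    ``ci='log'`` (default) computes the interval on the log-survival scale,
    S * exp(+-z * se(log S)), clipped to [0, 1]; ``ci='plain'`` uses the
    Greenwood standard error directly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")

    event_times = np.unique(times[events == 1])
    S, csum = 1.0, 0.0
    surv, var, lo, hi, n_risk, n_ev = [], [], [], [], [], []
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    for t in event_times:
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        S *= 1.0 - d / n
        if n > d:
            csum += d / (n * (n - d))
        else:
            csum = np.inf
        greenwood = S * S * csum
        if ci == "log":
            if S > 0 and np.isfinite(csum):
                half = z * np.sqrt(csum)
                lo_t, hi_t = S * np.exp(-half), S * np.exp(half)
            else:
                lo_t = hi_t = S
        elif ci == "plain":
            half = z * np.sqrt(greenwood) if np.isfinite(greenwood) else 0.0
            lo_t, hi_t = S - half, S + half
        else:
            raise ValueError("ci must be 'log' or 'plain'")
        surv.append(S)
        var.append(greenwood if np.isfinite(greenwood) else 0.0)
        lo.append(min(max(lo_t, 0.0), 1.0))
        hi.append(min(max(hi_t, 0.0), 1.0))
        n_risk.append(n)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        variance=np.asarray(var),
        ci_lower=np.asarray(lo),
        ci_upper=np.asarray(hi),
        n_at_risk=np.asarray(n_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
    )


# ---------------------------------------------------------------------------
# Log-rank test and O/E hazard ratio
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float
    observed: pd.Series  # per group
    expected: pd.Series


def logrank(groups, times, events) -> LogrankResult:
    """k-group log-rank test with hypergeometric variance at each event time.

    Ties are handled inside the hypergeometric moments. Supports k > 2
    groups; the statistic uses a generalized inverse of the (k-1)x(k-1)
    covariance block, and p comes from chi-square with k-1 df.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for gi, lab in enumerate(labels):
        if (gidx == gi).sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int(((times == t) & (events == 1)).sum())
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            mult = d_j * (n_j - d_j) / (n_j - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))

    u = (O - E)[:-1]
    v = V[:-1, :-1]
    if u.size == 0 or not np.any(v):
        chi = 0.0
    else:
        chi = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi, df))
    return LogrankResult(
        chi_square=chi,
        df=df,
        p_value=p,
        observed=pd.Series(O, index=labels),
        expected=pd.Series(E, index=labels),
    )


def hazard_ratio_from_logrank(observed: pd.Series, expected: pd.Series,
                              high_group) -> float:
    """HR = (O_high / E_high) / (O_low / E_low) from the log-rank table.

    Returns ``inf`` when the low group observed no events and ``0.0`` when
    the high group observed none (flagged values, not errors).
    """
    if len(observed) != 2 or len(expected) != 2:
        raise ValueError("O/E hazard ratio is defined for exactly two groups")
    if high_group not in observed.index:
        raise ValueError(f"unknown high-risk group {high_group!r}")
    (low_group,) = [g for g in observed.index if g != high_group]
    if expected[high_group] == 0 or expected[low_group] == 0:
        raise ValueError("expected event count of zero in a group")
    rate_high = observed[high_group] / expected[high_group]
    rate_low = observed[low_group] / expected[low_group]
    if rate_low == 0.0:
        return np.inf
    if rate_high == 0.0:
        return 0.0
    return float(rate_high / rate_low)


def logrank_hr(groups, times, events, high_group="high"):
    """Convenience: two-group log-rank plus O/E hazard ratio."""
    res = logrank(groups, times, events)
    hr = hazard_ratio_from_logrank(res.observed, res.expected, high_group)
    return hr, res


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

def concordance_index(risks, times, events) -> float:
    """Harrell's C over comparable pairs.

    A pair is comparable when the shorter observed time carries an event
    (a subject censored before the other's time is not comparable; pairs of
    two censored subjects never are). Concordance means the higher risk went
    with the shorter time; tied risks count 1/2.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(risks)
    if n < 2:
        raise ValueError("need >= 2 subjects")

    # vectorized over the i<j upper triangle expanded to ordered pairs:
    # pair (short, long) comparable iff t_s < t_l and e_s == 1, or
    # t_s == t_l with e_s == 1, e_l == 0 (the censored one outlived).
    ti, tj = times[:, None], times[None, :]
    ei, ej = events[:, None], events[None, :]
    ri, rj = risks[:, None], risks[None, :]
    comparable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all subjects censored?)")
    concordant = (comparable & (ri > rj)).sum()
    tied = (comparable & (ri == rj)).sum()
    return float((concordant + 0.5 * tied) / n_pairs)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_auc(risks, outcome, threshold: float) -> ROCResult:
    """ROC over all cutpoints; AUC from the Mann-Whitney rank identity.

    ``outcome`` is the binary recurrence indicator; a subject is predicted
    recurrent when risk > threshold. Ties in risk contribute 1/2 to the AUC.
    """
    risks = np.asarray(risks, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    ranks = stats.rankdata(risks)  # average ranks handle ties
    auc = float((ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))

    order = np.argsort(-risks, kind="stable")
    sorted_risk = risks[order]
    sorted_y = outcome[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_risk))[0], len(risks) - 1]
    tps = np.cumsum(sorted_y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, sorted_risk[distinct]]

    pred = risks > threshold
    tp = int((pred & (outcome == 1)).sum())
    tn = int((~pred & (outcome == 0)).sum())
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        accuracy=(tp + tn) / len(outcome),
        sensitivity=tp / n1,
        specificity=tn / n0,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# Welch's t and the Spearman randomization test
# ---------------------------------------------------------------------------

def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def spearman_permutation(x, y, n_perm: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Spearman rho with a two-sided randomization p-value.

    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1) over random
    permutations of ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = (rx - rx.mean()) / rx.std(ddof=0)
    ry_c = (ry - ry.mean()) / ry.std(ddof=0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry_c)
        r = float(rx_c @ perm) / len(x)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Covariate prognosis table
# ---------------------------------------------------------------------------

def covariate_prognosis(
    outcomes: pd.DataFrame,
    covariates: dict[str, str],
) -> pd.DataFrame:
    """Log-rank prognosis of clinical covariates, one row per covariate.

    ``covariates`` maps column name -> 'continuous' or 'categorical'.
    Patients missing a covariate are dropped for that covariate (N reports
    the retained count). Continuous covariates are dichotomized at their
    median (strictly greater -> 'high'); categorical levels are used as-is.
    The hazard ratio (O/E ratio, second/first sorted level or high/low) is
    reported only for two-group covariates.
    """
    rows = []
    times_all = outcomes["time_months"]
    events_all = outcomes["event"]
    for name, kind in covariates.items():
        if name not in outcomes.columns:
            raise ValueError(f"covariate {name!r} absent from outcomes")
        col = outcomes[name]
        keep = col.notna()
        col, times, events = col[keep], times_all[keep], events_all[keep]
        if kind == "continuous":
            med = float(np.median(col.astype(float)))
            groups = np.where(col.astype(float) > med, "high", "low")
        elif kind == "categorical":
            groups = col.astype(str).to_numpy()
        else:
            raise ValueError(f"covariate kind must be continuous/categorical, got {kind!r}")
        levels = np.unique(groups)
        if len(levels) < 2:
            raise ValueError(f"covariate {name!r} has a single level after dropping missing values")
        res = logrank(groups, times.to_numpy(dtype=float), events.to_numpy(dtype=int))
        if len(levels) == 2:
            high = "high" if "high" in levels else sorted(levels)[1]
            hr = hazard_ratio_from_logrank(res.observed, res.expected, high)
        else:
            hr = np.nan
        rows.append({"covariate": name, "HR": hr, "p_value": res.p_value,
                     "N": int(keep.sum()), "n_groups": len(levels)})
    return pd.DataFrame(rows).set_index("covariate")
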