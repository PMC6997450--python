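"""nCounter-style normalization: positive controls, background, housekeeping,
log2, per-gene z-scores.

The chain follows the conventional nCounter order and is exposed both as
stage functions operating on :class:`ProbeCountMatrix` and as the
scikit-learn style :class:`NanoStringNormalizer` transformer. Scaling
factors use the arithmetic mean of per-sample geometric means as the
reference level (the ``housekeeping.geo.mean`` convention), so each factor
vector averages to 1 on the data it was fitted on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import HOUSEKEEPING_GENES, NormalizedMatrix, ProbeCountMatrix

BACKGROUND_METHODS = ("mean", "mean2sd", "max")


def _geometric_means(block: pd.DataFrame, kind: str) -> pd.Series:
    vals = block.to_numpy(dtype=float)
    if (vals <= 0).any():
        rows, cols = np.nonzero(vals <= 0)
        sample = block.columns[cols[0]]
        probe = block.index[rows[0]]
        raise ValueError(
            f"nonpositive {kind} count for probe {probe!r} in sample {sample!r}: "
            "cannot take geometric mean"
        )
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=block.columns)


def positive_control_factors(counts: ProbeCountMatrix) -> pd.Series:
    """Per-sample scale factors from the positive-control probes."""
    pos = counts.probes_of("Positive")
    if len(pos) == 0:
        raise ValueError("no Positive-class probes present")
    geo = _geometric_means(counts.counts.loc[pos], "positive-control")
    return geo.mean() / geo


def positive_control_normalize(
    counts: ProbeCountMatrix,
) -> tuple[ProbeCountMatrix, pd.Series]:
    """Remove lane-wise technical variation using positive-control probes.

    Each sample's factor is (mean over samples of positive-probe geometric
    means) / (that sample's geometric mean); all of the sample's probe
    counts are multiplied by its factor.
    """
    factors = positive_control_factors(counts)
    out = counts.copy()
    out.counts = out.counts.astype(float).mul(factors, axis=1)
    return out, factors


def background_correct(counts: ProbeCountMatrix, method: str = "mean") -> ProbeCountMatrix:
    """Subtract a per-sample background level estimated from negative probes.

    ``method`` selects the level: mean (default), mean + 2*SD (sample SD,
    n-1 denominator) or max of the negative-control counts. Non-negative-
    class probes are floored at zero; negative rows are left as-is.
    """
    if method not in BACKGROUND_METHODS:
        raise ValueError(f"unknown background method {method!r}; use one of {BACKGROUND_METHODS}")
    neg = counts.probes_of("Negative")
    if len(neg) == 0:
        raise ValueError("no Negative-class probes present")
    block = counts.counts.loc[neg].astype(float)
    if method == "mean":
        b = block.mean(axis=0)
    elif method == "mean2sd":
        b = block.mean(axis=0) + 2.0 * block.std(axis=0, ddof=1)
    else:
        b = block.max(axis=0)
    out = counts.copy()
    other = counts.counts.index.difference(neg)
    corrected = out.counts.astype(float)
    corrected.loc[other] = (corrected.loc[other] - b).clip(lower=0.0)
    out.counts = corrected
    out.counts.attrs["background"] = b
    return out


def housekeeping_factors(
    counts: ProbeCountMatrix, hk_genes: tuple[str, ...] = HOUSEKEEPING_GENES
) -> pd.Series:
    """Per-sample RNA-content factors from housekeeping geometric means."""
    missing = [g for g in hk_genes if g not in counts.counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    block = counts.counts.loc[list(hk_genes)].astype(float)
    vals = block.to_numpy()
    if (vals <= 0).any():
        rows, cols = np.nonzero(vals <= 0)
        raise ValueError(
            f"housekeeping gene {block.index[rows[0]]!r} has nonpositive count "
            f"in sample {block.columns[cols[0]]!r} after background correction"
        )
    geo = pd.Series(np.exp(np.log(vals).mean(axis=0)), index=block.columns)
    return geo.mean() / geo


def housekeeping_normalize(
    counts: ProbeCountMatrix, hk_genes: tuple[str, ...] = HOUSEKEEPING_GENES
) -> tuple[ProbeCountMatrix, pd.Series]:
    """Scale Endogenous (and Housekeeping) counts for RNA-content variation."""
    factors = housekeeping_factors(counts, hk_genes)
    out = counts.copy()
    rows = counts.counts.index[counts.probe_class.isin(["Endogenous", "Housekeeping"])]
    scaled = out.counts.astype(float)
    scaled.loc[rows] = scaled.loc[rows].mul(factors, axis=1)
    out.counts = scaled
    return out, factors


def log_zscore(
    counts: ProbeCountMatrix,
    pseudocount: float = 1.0,
    per_batch: bool = False,
) -> NormalizedMatrix:
    """log2(count + 1), then per-gene z-scores across all retained samples.

    Sample SD uses the n-1 denominator. Constant genes get an all-zero row
    and are flagged (with a warning) rather than raising.
    """
    endo = counts.counts.index[counts.probe_class == "Endogenous"]
    block = counts.counts.loc[endo].astype(float)
    if block.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    if (block.to_numpy() < 0).any():
        raise ValueError("normalized counts must be >= 0 before log transform")
    logged = np.log2(block + pseudocount)

    def _z(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        mu = frame.mean(axis=1)
        sd = frame.std(axis=1, ddof=1)
        const = sd.index[sd == 0.0].tolist()
        safe = sd.replace(0.0, 1.0)
        z = frame.sub(mu, axis=0).div(safe, axis=0)
        z.loc[const] = 0.0
        return z, const

    if per_batch:
        if counts.batch is None:
            raise ValueError("per-batch z-scoring requires batch labels")
        parts = []
        const_all: set[str] = set()
        for _, cols in counts.batch.groupby(counts.batch):
            z, const = _z(logged[cols.index])
            parts.append(z)
            const_all.update(const)
        zscores = pd.concat(parts, axis=1)[block.columns]
        constant = sorted(const_all)
    else:
        zscores, constant = _z(logged)
    if constant:
        warnings.warn(f"constant genes z-scored to zero: {constant}", stacklevel=2)
    return NormalizedMatrix(values=zscores, stage="zscore",
                            steps=["log2+%g" % pseudocount, "zscore"],
                            constant_genes=constant, batch=counts.batch)


class NanoStringNormalizer(BaseEstimator, TransformerMixin):
    """Full normalization chain as a scikit-learn transformer.

    Order is fixed: positive-control scaling -> background subtraction ->
    housekeeping scaling -> log2 -> per-gene z-score. ``fit`` learns the
    cohort-level reference quantities (mean positive/housekeeping geometric
    means, per-gene log means and SDs); ``transform`` normalizes a matrix
    against them, so ``fit_transform`` on a cohort reproduces the standard
    pooled analysis while held-out samples can be mapped onto the same
    scale.

    Parameters
    ----------
    background_method : {'mean', 'mean2sd', 'max'}
        Per-sample background level from negative controls.
    hk_genes : housekeeping probe names used for content normalization.
    pseudocount : added before log2.
    per_batch_zscore : z-score within each batch instead of pooled.
    """

    def __init__(
        self,
        background_method: str = "mean",
        hk_genes: tuple[str, ...] = HOUSEKEEPING_GENES,
        pseudocount: float = 1.0,
        per_batch_zscore: bool = False,
    ) -> None:
        self.background_method = background_method
        self.hk_genes = hk_genes
        self.pseudocount = pseudocount
        self.per_batch_zscore = per_batch_zscore

    def _chain_to_log(self, X: ProbeCountMatrix):
        scaled, pos_factors = positive_control_normalize(X)
        corrected = background_correct(scaled, self.background_method)
        background = corrected.counts.attrs["background"]
        content, hk = housekeeping_normalize(corrected, tuple(self.hk_genes))
        endo = content.counts.index[content.probe_class == "Endogenous"]
        logged = np.log2(content.counts.loc[endo].astype(float) + self.pseudocount)
        return logged, pos_factors, background, hk

    def fit(self, X: ProbeCountMatrix, y=None) -> "NanoStringNormalizer":
        if X.n_samples < 2:
            raise ValueError("need at least 2 samples to fit z-score parameters")
        logged, pos_factors, background, hk = self._chain_to_log(X)
        pos = X.probes_of("Positive")
        self.positive_reference_ = float(
            _geometric_means(X.counts.loc[pos], "positive-control").mean()
        )
        self.positive_factors_ = pos_factors
        self.background_ = background
        self.housekeeping_factors_ = hk
        # hk reference measured on this cohort after its own pos/background steps
        corrected = background_correct(
            positive_control_normalize(X)[0], self.background_method
        )
        hk_block = corrected.counts.loc[list(self.hk_genes)].astype(float)
        self.housekeeping_reference_ = float(
            np.exp(np.log(hk_block.to_numpy()).mean(axis=0)).mean()
        )
        self.gene_means_ = logged.mean(axis=1)
        self.gene_sds_ = logged.std(axis=1, ddof=1)
        self.genes_ = logged.index
        if self.per_batch_zscore and X.batch is None:
            raise ValueError("per-batch z-scoring requires batch labels")
        return self

    def transform(self, X: ProbeCountMatrix) -> NormalizedMatrix:
        if not hasattr(self, "gene_means_"):
            raise ValueError("NanoStringNormalizer is not fitted")
        pos = X.probes_of("Positive")
        geo = _geometric_means(X.counts.loc[pos], "positive-control")
        pos_factors = self.positive_reference_ / geo
        scaled = X.copy()
        scaled.counts = scaled.counts.astype(float).mul(pos_factors, axis=1)
        corrected = background_correct(scaled, self.background_method)
        background = corrected.counts.attrs["background"]
        hk_block = corrected.counts.loc[list(self.hk_genes)].astype(float)
        if (hk_block.to_numpy() <= 0).any():
            raise ValueError("housekeeping counts nonpositive after background correction")
        hk = self.housekeeping_reference_ / pd.Series(
            np.exp(np.log(hk_block.to_numpy()).mean(axis=0)), index=hk_block.columns
        )
        content = corrected.copy()
        rows = content.counts.index[content.probe_class.isin(["Endogenous", "Housekeeping"])]
        vals = content.counts.astype(float)
        vals.loc[rows] = vals.loc[rows].mul(hk, axis=1)
        content.counts = vals
        if self.per_batch_zscore:
            nm = log_zscore(content, self.pseudocount, per_batch=True)
            nm.positive_factors = pos_factors
            nm.background = background
            nm.housekeeping_factors = hk
            nm.steps = ["positive", self.background_method, "housekeeping"] + nm.steps
            return nm
        logged = np.log2(
            content.counts.loc[self.genes_].astype(float) + self.pseudocount
        )
        const = self.gene_sds_.index[self.gene_sds_ == 0.0].tolist()
        safe = self.gene_sds_.replace(0.0, 1.0)
        z = logged.sub(self.gene_means_, axis=0).div(safe, axis=0)
        z.loc[const] = 0.0
        if const:
            warnings.warn(f"constant genes z-scored to zero: {const}", stacklevel=2)
        return NormalizedMatrix(
            values=z,
            stage="zscore",
            steps=["positive", self.background_method, "housekeeping",
                   "log2+%g" % self.pseudocount, "zscore"],
            positive_factors=pos_factors,
            background=background,
            housekeeping_factors=hk,
            constant_genes=const,
            batch=X.batch,
        )


def normalize_pipeline(
    counts: ProbeCountMatrix,
    background_method: str = "mean",
    hk_genes: tuple[str, ...] = HOUSEKEEPING_GENES,
    pseudocount: float = 1.0,
    per_batch_zscore: bool = False,
) -> NormalizedMatrix:
    """Run the full chain on one cohort (fit and transform on the same data)."""
    norm = NanoStringNormalizer(
        background_method=background_method,
        hk_genes=hk_genes,
        pseudocount=pseudocount,
        per_batch_zscore=per_batch_zscore,
    )
    return norm.fit(counts).transform(counts)
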