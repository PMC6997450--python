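"""Core containers shared across the pipeline.

Probe counts are held as a pandas DataFrame (probes x samples) together with
per-probe class labels following the nCounter convention (Endogenous,
Positive, Negative, Housekeeping) and optional per-sample batch labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("Endogenous", "Positive", "Negative", "Housekeeping")

#: The 4-gene recurrence signature and its fixed, published coefficients.
SIGNATURE_GENES = ("MMP1", "COL4A1", "P4HA2", "THBS2")
SIGNATURE_COEFFICIENTS = (0.25, 0.63, 0.45, 0.34)

HOUSEKEEPING_GENES = ("GAPDH", "RPS18")


@dataclass
class ProbeCountMatrix:
    """Raw or partially normalized probe counts.

    Parameters
    ----------
    counts : DataFrame, probes x samples. Raw input must be nonnegative;
        normalization stages produce real-valued counts.
    probe_class : Series mapping probe name -> class in ``PROBE_CLASSES``.
    nominal_conc : optional Series of nominal concentrations (fM) for
        positive-control probes.
    batch : optional Series mapping sample id -> batch label.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    nominal_conc: pd.Series | None = None
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe names: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = self.counts.index.difference(self.probe_class.index)
        if len(missing):
            raise ValueError(f"probes without a class label: {missing.tolist()}")
        self.probe_class = self.probe_class.reindex(self.counts.index)
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        if (np.asarray(self.counts, dtype=float) < 0).any():
            raise ValueError("negative counts are not allowed")

    # -- convenience views -------------------------------------------------
    def probes_of(self, probe_class: str) -> pd.Index:
        return self.counts.index[self.probe_class == probe_class]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "ProbeCountMatrix":
        return ProbeCountMatrix(
            counts=self.counts.copy(),
            probe_class=self.probe_class.copy(),
            nominal_conc=None if self.nominal_conc is None else self.nominal_conc.copy(),
            batch=None if self.batch is None else self.batch.copy(),
        )


@dataclass
class NormalizedMatrix:
    """Genes x samples expression values with a record of applied steps.

    ``stage`` is one of ``corrected_counts`` (after control-based scaling and
    background subtraction), ``log`` or ``zscore``.
    """

    values: pd.DataFrame
    stage: str
    steps: list[str] = field(default_factory=list)
    positive_factors: pd.Series | None = None
    background: pd.Series | None = None
    housekeeping_factors: pd.Series | None = None
    constant_genes: list[str] = field(default_factory=list)
    batch: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Margin -> patient annotation: index sample_id, column ``patient_id``."""
    if "patient_id" not in annotation.columns:
        raise ValueError("annotation requires a 'patient_id' column")
    if annotation.index.duplicated().any():
        dups = annotation.index[annotation.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in annotation: {dups}")
    return annotation


def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient outcomes: index patient_id, columns event, time_months, age."""
    for col in ("event", "time_months"):
        if col not in outcomes.columns:
            raise ValueError(f"outcomes require a '{col}' column")
    if not outcomes["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if (outcomes["time_months"] <= 0).any():
        bad = outcomes.index[outcomes["time_months"] <= 0].tolist()
        raise ValueError(f"nonpositive survival time for patients: {bad}")
    if outcomes.index.duplicated().any():
        dups = outcomes.index[outcomes.index.duplicated()].tolist()
        raise ValueError(f"duplicate patient ids in outcomes: {dups}")
    return outcomes
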