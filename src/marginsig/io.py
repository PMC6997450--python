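"""Readers and writers for the plain-text interchange formats.

Counts travel as TSV with ``CodeClass`` and ``Name`` columns followed by one
column per sample; clinical data as CSV with one row per margin sample
carrying the patient-level outcome columns (validated for within-patient
consistency on read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PROBE_CLASSES,
    ProbeCountMatrix,
    validate_annotation,
    validate_outcomes,
)

OUTCOME_COLS = ("event", "time_months")


def read_counts(path: str | Path) -> ProbeCountMatrix:
    """Read a counts TSV (CodeClass, Name, one column per sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("CodeClass", "Name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad_class = df.loc[~df["CodeClass"].isin(PROBE_CLASSES)]
    if len(bad_class):
        line = bad_class.index[0] + 2  # header is line 1
        raise ValueError(
            f"{path}:{line}: unknown CodeClass {bad_class['CodeClass'].iloc[0]!r}"
        )
    dup = df["Name"].duplicated()
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}:{line}: duplicate probe name {df['Name'][dup].iloc[0]!r}")
    sample_cols = [c for c in df.columns if c not in ("CodeClass", "Name", "Concentration")]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    columns = {}
    for c in sample_cols:
        try:
            vals = pd.to_numeric(df[c].to_numpy()).astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric count in sample column {c!r}") from exc
        bad = (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{path}:{row + 2}: non-integer or negative count in column {c!r}"
            )
        columns[c] = vals
    counts = pd.DataFrame(columns, index=df["Name"]).astype(np.int64)
    probe_class = pd.Series(df["CodeClass"].to_numpy(), index=df["Name"])
    nominal = None
    if "Concentration" in df.columns:
        conc = pd.to_numeric(df["Concentration"], errors="coerce")
        nominal = pd.Series(conc.to_numpy(), index=df["Name"]).dropna()
    return ProbeCountMatrix(counts=counts, probe_class=probe_class, nominal_conc=nominal)


def write_counts(matrix: ProbeCountMatrix, path: str | Path) -> None:
    out = pd.DataFrame({
        "CodeClass": matrix.probe_class.to_numpy(),
        "Name": matrix.counts.index,
    })
    if matrix.nominal_conc is not None:
        out["Concentration"] = [
            matrix.nominal_conc.get(p, np.nan) for p in matrix.counts.index
        ]
    counts = matrix.counts.reset_index(drop=True)
    out = pd.concat([out, counts], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the per-margin clinical CSV into (annotation, outcomes).

    Required columns: sample_id, patient_id, event, time_months. Optional:
    batch, age and any further covariates. Outcome columns must agree
    across a patient's rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("sample_id", "patient_id", *OUTCOME_COLS):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    if df[list(OUTCOME_COLS)].isna().any().any():
        raise ValueError(f"{path}: missing event/time values are not permitted")

    ann_cols = {"patient_id": df["patient_id"].astype(str).to_numpy()}
    if "batch" in df.columns:
        ann_cols["batch"] = df["batch"].to_numpy()
    annotation = pd.DataFrame(ann_cols, index=pd.Index(df["sample_id"].astype(str),
                                                      name="sample_id"))

    patient_cols = [c for c in df.columns if c not in ("sample_id", "batch")]
    per_patient = df[patient_cols].drop_duplicates()
    conflicted = per_patient["patient_id"][per_patient["patient_id"].duplicated()]
    if len(conflicted):
        raise ValueError(
            f"{path}: conflicting outcome rows for patient {conflicted.iloc[0]!r}"
        )
    outcomes = per_patient.set_index(per_patient["patient_id"].astype(str)).drop(
        columns="patient_id"
    )
    outcomes.index.name = "patient_id"
    return validate_annotation(annotation), validate_outcomes(outcomes)


def write_clinical(annotation: pd.DataFrame, outcomes: pd.DataFrame,
                   path: str | Path) -> None:
    df = annotation.reset_index()
    df = df.merge(outcomes.reset_index(), on="patient_id", how="left")
    df.to_csv(path, index=False)


def check_consistency(matrix: ProbeCountMatrix, annotation: pd.DataFrame) -> None:
    """Every counts sample must be annotated."""
    missing = matrix.sample_ids.difference(annotation.index)
    if len(missing):
        raise ValueError(f"counts samples missing from annotation: {missing.tolist()}")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default,
                                     allow_nan=True) + "\n")
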