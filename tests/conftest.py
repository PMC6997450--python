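import numpy as np
import pandas as pd
import pytest

from marginsig import (
    AnalysisConfig,
    ProbeCountMatrix,
    SimConfig,
    normalize_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort (62 patients, effect 1.5)."""
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    counts, annotation, outcomes, truth = default_cohort
    return normalize_pipeline(counts), annotation, outcomes, truth


@pytest.fixture()
def tiny_counts():
    """Hand-sized matrix: 2 endogenous, 1 housekeeping, 2 positive, 2 negative."""
    counts = pd.DataFrame(
        {
            "s1": [10, 40, 20, 100, 400, 0, 0],
            "s2": [12, 44, 20, 100, 400, 0, 0],
            "s3": [8, 36, 20, 100, 400, 0, 0],
        },
        index=["MMP1", "COL4A1", "GAPDH", "POS_A", "POS_B", "NEG_A", "NEG_B"],
    )
    probe_class = pd.Series(
        ["Endogenous", "Endogenous", "Housekeeping", "Positive", "Positive",
         "Negative", "Negative"],
        index=counts.index,
    )
    return ProbeCountMatrix(counts=counts, probe_class=probe_class)


def make_counts(pos, neg, hk, endo, samples=None):
    """Assemble a ProbeCountMatrix from per-class row dicts."""
    rows = {}
    classes = {}
    for d, cls in ((endo, "Endogenous"), (hk, "Housekeeping"),
                   (pos, "Positive"), (neg, "Negative")):
        for name, vals in d.items():
            rows[name] = vals
            classes[name] = cls
    counts = pd.DataFrame(rows).T
    if samples is not None:
        counts.columns = samples
    else:
        counts.columns = [f"s{i+1}" for i in range(counts.shape[1])]
    return ProbeCountMatrix(counts=counts, probe_class=pd.Series(classes))


@pytest.fixture(scope="session")
def memory_config():
    return AnalysisConfig(counts="<memory>", clinical="<memory>", n_reps=100)
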