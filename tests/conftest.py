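import numpy as np
import pandas as pd
import pytest

from psnet import PatientDataset, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """40 patients, 5 feature groups (1 planted), strong effect."""
    ds, rules, truth = generate_synthetic_dataset(
        n_patients=40,
        layers={"expression": {"n_features": 5, "group_size": 8,
                               "metric": "pearson"}},
        n_discriminative=1,
        effect_size=2.0,
        seed=7,
    )
    return ds, rules, truth


@pytest.fixture
def tiny_two_layer():
    """Hand-built 10-patient dataset with an expression and a clinical layer."""
    rng = np.random.default_rng(3)
    ids = [f"P{i}" for i in range(10)]
    labels = {pid: ("A" if i < 5 else "B") for i, pid in enumerate(ids)}
    # class-specific expression profiles over 6 measures
    base = {"A": rng.normal(size=6), "B": rng.normal(size=6)}
    expr = pd.DataFrame(
        {pid: base[labels[pid]] + 0.3 * rng.normal(size=6) for pid in ids},
        index=[f"g{k}" for k in range(6)],
    )
    clin = pd.DataFrame(
        {pid: [float(i)] for i, pid in enumerate(ids)}, index=["age"]
    )
    ds = PatientDataset(ids=ids, labels=labels,
                        assays={"expression": expr, "clinical": clin})
    rules = {"expression": {"expr_path": [f"g{k}" for k in range(6)]},
             "clinical": {"age": ["age"]}}
    metrics = {"expression": "pearson", "clinical": "normdiff"}
    return ds, rules, metrics
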