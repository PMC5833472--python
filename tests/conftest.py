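import numpy as np
import pandas as pd
import pytest

from plasmet.core import FeatureTable
from plasmet.simulate import SimulationConfig, simulate_study


def make_table(
    values,
    groups=None,
    batches=None,
    injections=None,
    is_qc=None,
    scale="raw",
    feature_ids=None,
):
    """Hand-build a small FeatureTable from a 2-D array (NaN = missing)."""
    values = np.asarray(values, float)
    n, p = values.shape
    sample_ids = [f"S{i:02d}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j:02d}" for j in range(p)]
    is_qc = list(is_qc) if is_qc is not None else [False] * n
    groups = list(groups) if groups is not None else ["A"] * n
    groups = [None if q else g for g, q in zip(groups, is_qc)]
    batches = list(batches) if batches is not None else [1] * n
    injections = list(injections) if injections is not None else list(range(1, n + 1))
    X = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    samples = pd.DataFrame(
        {
            "group": groups,
            "batch": batches,
            "injection_index": injections,
            "is_qc": is_qc,
            "polarity": "positive",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "neutral_mass": np.linspace(100, 900, p),
            "rt_min": np.linspace(1, 30, p),
            "polarity": "positive",
            "annotation": None,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return FeatureTable(X, samples, features, scale=scale)


@pytest.fixture
def small_study():
    """Compact 3-group batched study with planted effects."""
    cfg = SimulationConfig(
        group_sizes={"I": 14, "II": 14, "III": 10},
        subgroup=("I", "Ia", 7),
        n_features=60,
        n_differential=8,
        effect_log2=1.5,
    )
    table, truth = simulate_study(cfg, seed=11)
    return table, truth


@pytest.fixture
def two_group_config():
    return SimulationConfig(
        group_sizes={"A": 20, "B": 20},
        subgroup=None,
        n_features=100,
        n_differential=10,
        effect_groups=("A",),
    )
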