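import numpy as np
import pandas as pd
import pytest

from metchalizer.core_io import FeatureTable, make_feature_meta
from metchalizer.synthetic import SimulationConfig, simulate_dataset


def small_table(n_batches=3, n_samples_per_batch=8, n_features=5, seed=0,
                with_qc=True, with_patients=False):
    """Hand-rolled small table for unit tests (no simulator involvement)."""
    rng = np.random.default_rng(seed)
    rows, values = [], []
    for b in range(n_batches):
        for i in range(n_samples_per_batch):
            cls = "qc" if with_qc and i < 2 else "control"
            rows.append((f"b{b}_s{i}", f"b{b}", float(rng.uniform(1, 70)),
                         rng.choice(["M", "F"]), cls, None, None))
            values.append(rng.lognormal(10, 0.5, size=n_features))
    if with_patients:
        for r in range(3):
            rows.append((f"b0_p0r{r}", "b0", 30.0, "F", "patient", "T0", "IEM_X"))
            values.append(rng.lognormal(10, 0.5, size=n_features))
    sample_meta = pd.DataFrame(
        rows, columns=["sample_id", "batch_id", "age", "sex", "class",
                       "triplicate_id", "iem_label"],
    ).set_index("sample_id")
    fids = [f"F{j}" for j in range(n_features)]
    abundance = pd.DataFrame(values, index=sample_meta.index, columns=fids)
    return FeatureTable(abundance=abundance,
                        sample_meta=sample_meta,
                        feature_meta=make_feature_meta(fids))


@pytest.fixture
def tiny_table():
    return small_table()


@pytest.fixture(scope="session")
def sim_small():
    """Small multi-batch simulation shared across tests (3 batches)."""
    cfg = SimulationConfig(
        n_batches=3, controls_per_batch=(18, 22), qc_replicates_per_batch=(5, 6),
        n_patients=6, n_features=30, n_internal_standards=6, rng_seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_studyscale():
    """Nine-batch simulation at study-like scale, shared across tests."""
    cfg = SimulationConfig(
        n_batches=9, controls_per_batch=(30, 30), qc_replicates_per_batch=(6, 6),
        n_patients=12, n_features=100, is_coupling=0.9, rng_seed=1,
    )
    return simulate_dataset(cfg)
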