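import numpy as np
import pandas as pd
import pytest

from possynth import AnalysisDataset, SimulationConfig, emit_reference_table, simulate_population
from possynth.data import from_records


def make_dataset(ages, sbp, w=None, gender=None, height=None, body_weight=None):
    """Small hand-built dataset; sbp may contain NaN (those units get r=0)."""
    n = len(ages)
    df = pd.DataFrame({
        "age": ages,
        "sbp": sbp,
        "w": w if w is not None else np.ones(n),
        "gender": gender if gender is not None else ["female"] * n,
        "height": height if height is not None else np.full(n, np.nan),
        "body_weight": body_weight if body_weight is not None else np.full(n, np.nan),
    })
    return from_records(df, source="test")


def random_dataset(rng, n=50, p_missing=0.2, with_height=True):
    """Random mixed-region dataset for oracle comparisons."""
    ages = rng.integers(2, 18, size=n)
    sbp = rng.normal(100 + ages, 8.0)
    observed = (ages >= 8) & (rng.random(n) > p_missing)
    sbp = np.where(observed, sbp, np.nan)
    height = rng.normal(80 + 5.5 * ages, 7.0) if with_height else np.full(n, np.nan)
    return make_dataset(
        ages=ages, sbp=sbp,
        w=rng.gamma(2.0, 1.0, size=n) + 0.2,
        gender=rng.choice(["male", "female"], size=n),
        height=height,
        body_weight=rng.normal(0.6 * (80 + 5.5 * ages), 4.0),
    )


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(n=2000, seed=11)


@pytest.fixture(scope="session")
def sim_ds(default_cfg):
    return simulate_population(default_cfg)


@pytest.fixture(scope="session")
def sim_table(default_cfg):
    return emit_reference_table(default_cfg)
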