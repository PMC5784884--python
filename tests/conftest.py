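"""Shared fixtures: small synthetic configurations sized for fast tests."""

import numpy as np
import pandas as pd
import pytest

from easead.containers import ConcentrationMatrix
from easead.synthetic import SyntheticConfig

SMALL_FAMILIES = {
    "acylcarnitine": 2, "amino acid": 2, "biogenic amine": 2,
    "glycerophospholipid": 3, "sphingolipid": 2, "hexose": 1,
}


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """A 12-metabolite null configuration with small cohorts."""
    defaults = dict(
        n_metabolites=12,
        family_composition=dict(SMALL_FAMILIES),
        group_sizes={"AD": 15, "CN": 14, "ASYMAD": 15},
        preclinical_group_sizes={"converter": 40, "non-converter": 40},
        prodromal_group_sizes={"CN": 25, "MCI": 40, "AD": 25},
        censor_time=8.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def null_config():
    return small_config()


@pytest.fixture
def tiny_matrix():
    """4 samples × 2 metabolites with a censored column (LOD 0.3)."""
    values = pd.DataFrame(
        {"m1": [0.1, 0.2, 0.5, 0.9], "m2": [1.0, 2.0, 3.0, 4.0]},
        index=["s1", "s2", "s3", "s4"],
    )
    flags = pd.DataFrame(
        {"m1": [True, True, False, False], "m2": [False] * 4},
        index=values.index,
    )
    lod = pd.Series({"m1": 0.3, "m2": 0.5})
    return ConcentrationMatrix(values, flags, lod)


@pytest.fixture
def blood_metadata():
    """Deterministic serum metadata: 250 samples, 43 with Met-So above 5 μM."""
    rng = np.random.default_rng(7)
    n = 250
    group = np.array(["converter"] * 126 + ["non-converter"] * 124)
    metso = rng.uniform(0.5, 4.5, n)
    # 34 converter and 9 non-converter samples pushed above the cutoff
    metso[:34] = rng.uniform(5.5, 9.0, 34)
    metso[126:135] = rng.uniform(5.5, 9.0, 9)
    return pd.DataFrame({
        "sample_id": [f"P{i:04d}" for i in range(n)],
        "subject_id": [f"P{i:04d}" for i in range(n)],
        "cohort": "preclinical", "group": group, "region": "none",
        "age": rng.normal(78, 7, n), "sex": rng.integers(0, 2, n),
        "storage_time": rng.uniform(5, 25, n), "metso": metso,
    })
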