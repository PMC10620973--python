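import numpy as np
import pandas as pd
import pytest

from conceptome import SimConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """Desk-scale simulation: full study design, reduced gene count."""
    params = dict(n_genes=600, n_de_embryo=30, n_de_yolk=10, n_de_shared=8,
                  n_stage_shared=30, n_stage_diabetic_only=30,
                  n_stage_reversed=8)
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated dataset + truth shared across read-only tests."""
    return simulate_dataset(small_config(), seed=7)


@pytest.fixture()
def toy_meta():
    """Two complete conceptuses (one per condition)."""
    rows = []
    for cid, cond, stage, sex in (("c1", "normal", 5, "female"),
                                  ("c2", "diabetic", 8, "male")):
        for tissue in ("embryo", "yolk_sac"):
            rows.append({"sample_id": f"{cid}_{tissue}", "tissue": tissue,
                         "condition": cond, "somite_pairs": stage,
                         "conceptus_id": cid, "sex": sex})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
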