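import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pollenomics as pk

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def small_sim_config(seed: int = 7) -> pk.SimConfig:
    """A reduced dataset for fast file/CLI round-trip tests."""
    return pk.SimConfig(
        n_genes=600,
        n_controls=8,
        n_direct_per_stage=20,
        n_delayed_per_stage=20,
        n_hs_up_transcript=10,
        n_hs_down_transcript=10,
        n_hs_up_protein=12,
        n_hs_down_protein=12,
        n_paired_groups=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    return pk.simulate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def default_recovery():
    """One full-scale recovery run shared across the suite."""
    rec, result, ds = pk.end_to_end_recovery(pk.SimConfig(seed=1), seed=11)
    return rec, result, ds


def make_matrix(values, stage_cond_rep, level="transcript", unit="TPM"):
    """Build an ExpressionMatrix from a dict of lib -> column values and
    a matching dict of lib -> (stage, condition, replicate)."""
    meta = pd.DataFrame(
        [
            {"library_id": lib, "level": level, "stage": s, "condition": c,
             "replicate": r}
            for lib, (s, c, r) in stage_cond_rep.items()
        ]
    ).set_index("library_id")
    return pk.ExpressionMatrix(pd.DataFrame(values), meta, unit)


@pytest.fixture
def two_rep_matrix():
    """3 genes x 2 replicates in a single (tetrad, CO) group."""
    return make_matrix(
        {"L1": [4.9, 6.0, 0.0], "L2": [6.0, 7.0, 8.0]},
        {"L1": ("tetrad", "CO", 1), "L2": ("tetrad", "CO", 2)},
    )
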