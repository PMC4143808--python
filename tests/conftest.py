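import numpy as np
import pandas as pd
import pytest

from longfam.pedigree import Pedigree, compute_kinship
from longfam.phenotypes import medication_preadjust
from longfam.simdata import PedigreeTemplate, SimulationConfig, simulate_dataset


def make_pedigree(rows):
    """Build a Pedigree from (fid, iid, father, mother, sex) tuples."""
    return Pedigree(
        members=pd.DataFrame(
            rows, columns=["fid", "iid", "father", "mother", "sex"]
        ).astype(object)
    )


@pytest.fixture(scope="session")
def trio():
    return make_pedigree(
        [
            ("F1", "dad", None, None, "male"),
            ("F1", "mom", None, None, "female"),
            ("F1", "kid", "dad", "mom", "male"),
        ]
    )


@pytest.fixture(scope="session")
def three_gen_pedigree():
    """Default 12-member, 4-founder three-generation template pedigree."""
    cfg = SimulationConfig(n_pedigrees=1, n_unrelated_extra=0, n_common=1,
                           n_transcripts=1, rare_per_transcript=1)
    from longfam.simdata import simulate_pedigrees

    return simulate_pedigrees(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """One seeded desk-scale replicate shared across read-only tests."""
    cfg = SimulationConfig(
        seed=7,
        n_pedigrees=8,
        n_unrelated_extra=30,
        n_common=60,
        n_transcripts=6,
        rare_per_transcript=6,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_sim_adjusted(small_sim):
    return medication_preadjust(small_sim.phenotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
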