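import numpy as np
import pandas as pd
import pytest

from methsub.simulate import SimulationConfig, generate_methylation_cohorts, generate_study


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """Reduced-size study configuration for fast unit tests."""
    params = dict(
        seed=seed,
        n_cpgs=1200,
        samples_per_group={"Control": 20, "LOAD-S1": 25, "LOAD-S2": 25,
                           "CohortSpecific": 15},
        signature_sizes={"S1": 80, "S2": 80, "sharedLOAD": 40,
                         "cohortSpecific": 60, "NFT-like": 60},
        expression={"n_genes": 400, "dispersion": 0.1, "n_degs": 30,
                    "fold_change": 2.0, "n_linked_pairs": 15, "link_slope": 6.0},
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config(), with_microglia=False, with_morphology=False)


@pytest.fixture(scope="session")
def full_study():
    """Study at the standard conditions (~5,000 CpGs, ~150 samples/cohort)."""
    return generate_study(SimulationConfig(seed=1), with_microglia=True,
                          with_morphology=True)


@pytest.fixture(scope="session")
def full_pipeline(full_study):
    from methsub.pipeline import run_discovery_replication
    return run_discovery_replication(full_study.beta_by_cohort,
                                     full_study.annotations, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
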