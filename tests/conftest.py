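import numpy as np
import pytest

from mtgs.kinship import additive_relationship, impute_missing
from mtgs.synthetic_data import (
    DesignSpec,
    SimParams,
    simulate_markers,
    simulate_trial,
)


@pytest.fixture(scope="session")
def small_markers():
    return simulate_markers(n_lines=60, n_markers=400, seed=11)


@pytest.fixture(scope="session")
def small_kinship(small_markers):
    return additive_relationship(small_markers)


@pytest.fixture(scope="session")
def two_trait_params():
    return SimParams(
        trait_names=("T1", "T2"),
        heritabilities={"T1": 0.5, "T2": 0.5},
        trait_means={"T1": 10.0, "T2": 5.0},
        trait_sds={"T1": 2.0, "T2": 1.0},
        genetic_correlations=np.array([[1.0, 0.6], [0.6, 1.0]]),
        gxe_to_resid={"T1": 1.0, "T2": 1.0},
    )


@pytest.fixture(scope="session")
def small_trial(two_trait_params):
    markers = simulate_markers(n_lines=63, n_markers=300, seed=21)
    design = DesignSpec(n_lines=60, n_checks=3, n_blocks_per_env=3,
                        environments=("E1", "E2", "E3"))
    trial, truth = simulate_trial(markers, design, two_trait_params, seed=22)
    return trial, truth, markers, design
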