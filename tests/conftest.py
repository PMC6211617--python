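import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svase.containers import EmbryoSpec
from svase.synthetic_data import (
    default_crm_model,
    random_truth_params,
    simulate_atlas_pair,
    simulate_svase_matrix,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def embryo():
    return EmbryoSpec("emb1", mother="mel", sex="female")


@pytest.fixture(scope="session")
def small_truth_matrix():
    """ASE matrix with 5 step, 5 peak and 50 null genes over 5 embryos."""
    rng = np.random.default_rng(21)
    steps = [random_truth_params("step", rng) for _ in range(5)]
    peaks = [random_truth_params("peak", rng) for _ in range(5)]
    matrix, truth = simulate_svase_matrix(
        50, steps, peaks, n_slices=26, noise_sd=0.05, seed=22, n_embryos=5
    )
    return matrix, truth


@pytest.fixture(scope="session")
def atlas_pair_hkb():
    """Paired atlases with the Huckebein coefficient doubled in species 2."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_atlas_pair(
            EmbryoSpec("atlas", mother="mel", sex="female"),
            default_crm_model(),
            "hkb",
            2.0,
            seed=31,
            n_nuclei=1500,
        )
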