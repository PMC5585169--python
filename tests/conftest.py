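import numpy as np
import pytest

from msmelt.melt_simulator import (
    EDARADD,
    ELOVL2,
    default_aging_models,
    default_marker_models,
)


@pytest.fixture(scope="session")
def marker_models():
    return default_marker_models()


@pytest.fixture(scope="session")
def noiseless_models(marker_models):
    from dataclasses import replace

    return {m: replace(mod, noise_sd=0.0) for m, mod in marker_models.items()}


@pytest.fixture(scope="session")
def aging_models():
    return default_aging_models()


@pytest.fixture(scope="session")
def small_cohort():
    """197-donor training cohort with true scores only (no melt curves)."""
    from msmelt.melt_simulator import CohortSpec, TRAINING_STRATA, simulate_cohort

    samples, _ = simulate_cohort(
        CohortSpec(TRAINING_STRATA), seed=7, include_curves=False
    )
    return samples.rename(columns={"m1_true": "m1", "m2_true": "m2"})
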