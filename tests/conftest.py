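"""Shared fixtures: one mid-size synthetic cohort and one latent-model fit
are built once per session and reused across test modules."""

import warnings

import pytest

import soundwell as sw
from soundwell.latent import LatentWellbeingModel

warnings.filterwarnings("ignore", module="statsmodels")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_truth():
    return sw.GeneratorTruth()


@pytest.fixture(scope="session")
def cohort(default_truth):
    """40 participants x 3 days x 50 bins (~150 epochs each), default truth."""
    return sw.generate_cohort(40, default_truth, days=3, bins_per_day=50, seed=1)


@pytest.fixture(scope="session")
def designs(cohort):
    profiles, effects, obs = cohort
    train, holdout, params, log = sw.run_preprocessing(obs, profiles)
    return train, holdout, params, log


@pytest.fixture(scope="session")
def fitted(designs):
    """Population latent-model fit at 4 x (500 warmup + 500 draws)."""
    train, _, _, _ = designs
    model = LatentWellbeingModel.from_design(train)
    return model.fit(draws=500, warmup=500, chains=4, seed=11)
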