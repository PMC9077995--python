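import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ecborrow import MapConfig, NormalMixture, fit_map, load_psp_historical, moment_match_normal
from ecborrow.mixtures import robustify


@pytest.fixture(scope="session")
def psp_studies():
    return load_psp_historical()


@pytest.fixture(scope="session")
def psp_fit(psp_studies):
    return fit_map(psp_studies, MapConfig())


@pytest.fixture(scope="session")
def psp_map_prior(psp_fit):
    return moment_match_normal(psp_fit)


@pytest.fixture(scope="session")
def psp_robust_prior(psp_map_prior):
    return robustify(psp_map_prior, 0.5, 15.0, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_mixture(weights, means, sds) -> NormalMixture:
    return NormalMixture.from_unnormalized(
        np.asarray(weights, float), np.asarray(means, float), np.asarray(sds, float)
    )
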