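import warnings

import numpy as np
import pytest

import bayesrct as brc

# the arviz import chain emits a refactor notice; irrelevant to results
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def amisulpride() -> brc.TwoByTwoTrial:
    return brc.worked_example()


@pytest.fixture(scope="session")
def amisulpride_draws(amisulpride) -> brc.PosteriorDraws:
    """Default-prior posterior for the worked example, 100k draws.

    Session-scoped: several tests summarize the same fit.
    """
    return brc.fit_posterior(
        amisulpride, sampler=brc.SamplerConfig(n_draws=100_000, seed=20_260_930)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(915)
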