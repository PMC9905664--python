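import warnings

import numpy as np
import pytest

import isowash as iw


@pytest.fixture(scope="session")
def small_fit():
    """A shared small-but-real hierarchical fit on a 2010-style simulation."""
    spec = iw.preset_2010(seed=42, n_birds=10, species=["broad_tailed"] * 5 + ["rufous"] * 5)
    data, truth = iw.simulate_population(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = iw.fit_hierarchical(
            data,
            iw.PriorSpec(),
            iw.MCMCConfig(n_iter=2000, n_burn=500, thin=3, seed=7),
        )
    return data, truth, samples


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
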