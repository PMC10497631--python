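import numpy as np
import pytest

import cl36soil as cs


@pytest.fixture(scope="session")
def truth():
    """Default virtual site truth (deterministic under its seed)."""
    return cs.gen_site(1)


@pytest.fixture(scope="session")
def noiseless_site(truth):
    """Observations with zero realized noise (uncertainties still recorded)."""
    return cs.gen_observations(truth, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_site(truth):
    return cs.gen_observations(truth, noise_seed=777)


@pytest.fixture(scope="session")
def default_sample(noisy_site):
    """One Monte-Carlo rejection run at the default replicate count."""
    dataset, _ = noisy_site
    return cs.run_mc(dataset, config=cs.MCConfig(n_simulations=10_000, seed=11))


@pytest.fixture(scope="session")
def posterior_runs(noisy_site):
    """Five independent rejection runs on the same site (MC-noise averaging)."""
    dataset, _ = noisy_site
    samples = [
        cs.run_mc(dataset, config=cs.MCConfig(n_simulations=10_000, seed=s))
        for s in range(11, 16)
    ]
    return [cs.summarize_posteriors(s).table for s in samples]


@pytest.fixture(scope="session")
def steady(truth):
    return truth.steady_state()


@pytest.fixture(scope="session")
def scenario(truth):
    return truth.scenario()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
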