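import numpy as np
import pytest

from surgact import GeneratorConfig, RSPRegressor, generate_dataset


@pytest.fixture(scope="session")
def toy_cohort():
    """40 default-condition trajectories: first 20 train, last 20 held out."""
    cfg = GeneratorConfig(n_trajectories=40, seed=0)
    trajectories, manifest = generate_dataset(cfg)
    return cfg, trajectories


@pytest.fixture(scope="session")
def trained_rsp(toy_cohort):
    """RSP model trained once on the 20 training videos (seeded)."""
    _, trajectories = toy_cohort
    return RSPRegressor(seed=0).fit([t.video for t in trajectories[:20]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
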