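import numpy as np
import pytest

from dynsig import GeneratorConfig, get_model
from dynsig.experiments import EXPERIMENT_MODELS, QPS_MODELS


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(runs_per_model=1, samples=1000, master_seed=7)


@pytest.fixture(scope="session")
def tiny_pools():
    """Small synthetic trajectory pools shaped like real ones (no ODE solves).

    Chaotic-model signals are high-amplitude noise, non-chaotic ones
    low-amplitude sinusoids — enough structure for split/counting tests.
    """
    rng = np.random.default_rng(123)
    s = 200

    def make(symbols, v):
        pool = {}
        for sym in symbols:
            dim = get_model(sym).dim
            if sym.startswith("CHA"):
                pool[sym] = rng.normal(scale=10.0, size=(v, s, dim))
            else:
                t = np.linspace(0, 20, s)
                base = np.sin(t)[None, :, None]
                pool[sym] = base + 0.1 * rng.normal(size=(v, s, dim))
        return pool

    train = make(EXPERIMENT_MODELS + QPS_MODELS, 8)
    test = make(EXPERIMENT_MODELS + QPS_MODELS, 4)
    return train, test
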