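import numpy as np
import pytest

from glyconet import GeneratorConfig, build_vocabulary, random_glycan


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def corpus(gen_cfg):
    rng = gen_cfg.rng()
    return [random_glycan(gen_cfg, rng) for _ in range(80)]


@pytest.fixture(scope="session")
def vocab(corpus):
    return build_vocabulary(corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
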