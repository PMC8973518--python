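import numpy as np
import pytest

from marseq.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A full synthetic study bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = simulate(outdir, SyntheticConfig(seed=11))
    return outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, at=0.62):
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
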