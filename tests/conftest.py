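import numpy as np
import pytest

from neurodensity import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smoke_corpus(tmp_path):
    """A written smoke corpus: cable + Y-tree SWC cells and a consensus XML."""
    d = tmp_path / "corpus"
    fx.write_corpus("smoke", d, seed=1)
    return d


def random_morphologies(n, rng):
    """n seeded random arbors for property checks."""
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [fx.make_random_tree(int(s), depth=3) for s in seeds]
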