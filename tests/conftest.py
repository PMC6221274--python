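import numpy as np
import pytest

from d2nnlm import GeneratorSpec, Transcript, make_groups


@pytest.fixture(scope="session")
def toy_transcripts() -> list[Transcript]:
    """Tiny fixed corpus used by hand-enumeration oracles."""
    return [
        Transcript("p1", "positive",
                   [["the", "boy", "is", "on", "the", "stool"],
                    ["the", "jar", "is", "full"]]),
        Transcript("c1", "control",
                   [["the", "boy", "is", "on", "the", "floor"]]),
    ]


@pytest.fixture(scope="session")
def synthetic_corpus() -> list[Transcript]:
    """A divergent two-group synthetic corpus shared by slower tests."""
    return make_groups(GeneratorSpec(divergence=0.8, seed=7))


@pytest.fixture(scope="session")
def separable_2d():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(-2.0, 0.6, (20, 2)), rng.normal(2.0, 0.6, (20, 2))])
    y = np.array(["control"] * 20 + ["positive"] * 20)
    return X, y
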