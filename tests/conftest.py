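import numpy as np
import pytest
from hypothesis import settings

from seedless.site_grammar import MirnaGuide

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

# guides used throughout: let-7a for worked examples, miR-155/miR-124 for
# the registers the pipeline was built around
LET7A = "UGAGGUAGUAGGUUGUAUAGUU"
MIR155 = "UUAAUGCUAAUCGUGAUAGGGGU"
MIR124 = "UAAGGCACGCGGUGAAUGCCAA"


@pytest.fixture(scope="session")
def let7a():
    return MirnaGuide("let-7a", LET7A)


@pytest.fixture(scope="session")
def mir155():
    return MirnaGuide("miR-155", MIR155)


@pytest.fixture(scope="session")
def mir124():
    return MirnaGuide("miR-124", MIR124)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_reads(rng, n, length=40):
    """Uniform random RNA reads as python strings."""
    idx = rng.integers(0, 4, size=(n, length))
    flat = np.frombuffer(b"ACGU", dtype=np.uint8)[idx].tobytes().decode()
    return [flat[i * length : (i + 1) * length] for i in range(n)]
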