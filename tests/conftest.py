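import numpy as np
import pytest

from rnathermscan import RnaSequence, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140409)


def random_rna(rng, n: int, weights=None) -> RnaSequence:
    bases = rng.choice(np.array(list("ACGU")), size=n, p=weights)
    return RnaSequence(f"rand{n}", "".join(bases))


def random_structure(rng: np.random.Generator, n: int):
    """Random valid structure by recursive nested sampling (test helper)."""
    from rnathermscan import SecondaryStructure

    pairs = []

    def fill(i, j):
        while i < j - 3:
            if rng.random() < 0.5:
                i += 1
                continue
            k = int(rng.integers(i + 4, j + 1))
            pairs.append((i + 1, k + 1))
            fill(i + 1, k - 1)
            i = k + 1

    fill(0, n - 1)
    return SecondaryStructure(length=n, pairs=frozenset(pairs))
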