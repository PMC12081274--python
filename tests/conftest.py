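import numpy as np
import pytest

from cbskit.io import GenomeIndex
from cbskit.motifs import PositionFrequencyMatrix, pfm_to_pwm


@pytest.fixture(scope="session")
def toy_pfm():
    """Asymmetric 3-position PFM: informative, with unequal minor counts."""
    counts = np.array([
        [8, 1, 2],
        [1, 8, 1],
        [0, 0, 6],
        [1, 1, 1],
    ], dtype=float)
    return PositionFrequencyMatrix(motif_id="TOY3", counts=counts)


@pytest.fixture(scope="session")
def toy_pwm(toy_pfm):
    return pfm_to_pwm(toy_pfm)


@pytest.fixture(scope="session")
def mid_pfm():
    """5-position PFM with a mix of strong and weak columns."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 30, size=(4, 5)).astype(float)
    counts[0, 0] = 90  # strong A at position 1
    counts[2, 3] = 70  # strong G at position 4
    return PositionFrequencyMatrix(motif_id="TOY5", counts=counts)


@pytest.fixture()
def random_genome():
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
    return GenomeIndex({"chr1": seq})
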