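import numpy as np
import pytest

from motifturnover import MotifMatrix, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def meme_text():
    return """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF MA0001.1 AT_hook
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
1.0 0.0 0.0 0.0
0.0 0.0 0.0 1.0

MOTIF MA0002.1 GC_box
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.1 0.4 0.4 0.1
0.0 0.5 0.5 0.0
0.25 0.25 0.25 0.25
"""


@pytest.fixture
def sharp_motif(rng):
    """High-information width-8 motif whose consensus passes p < 1e-4."""
    consensus = rng.integers(0, 4, size=8)
    probs = np.full((8, 4), 0.01)
    probs[np.arange(8), consensus] = 0.97
    return MotifMatrix("SHARP", "sharp", probs, "clusterA")


@pytest.fixture
def small_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def worked_example():
    """Target and reference cluster counts of the three-motif orthogroup."""
    return {"A": 1, "B": 0, "C": 2}, {"A": 1, "B": 1, "C": 1}
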