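import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import sclexo as sx


@pytest.fixture(scope="session")
def template():
    """The 224-bp standard with the first forward modified C at 0-based 28."""
    return sx.standard_fixture(seed=0)


@pytest.fixture(scope="session")
def paper_params():
    """Failure fractions estimated from the standard experiment."""
    return sx.DesignParameters(p_undigested=0.1238, p_nostall=0.5104)


@pytest.fixture(scope="session")
def sparse_ref():
    """200-CpG synthetic chromosome, CpGs farther apart than a read window."""
    ref, positions = sx.make_cpg_reference(n_cpgs=200, gap_range=(60, 140), seed=11)
    return ref, positions


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
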