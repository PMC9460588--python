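import numpy as np
import pytest

from chiasmap import build_bins, reference
from chiasmap.simulate import builtin_scenarios


@pytest.fixture
def rng():
    return np.random.default_rng(20220928)


@pytest.fixture(scope="session")
def paper_lines():
    return list(reference.deletion_lines()["name"])


@pytest.fixture(scope="session")
def paper_bins(paper_lines):
    return build_bins(paper_lines)


@pytest.fixture(scope="session")
def line_table():
    return reference.line_summaries().set_index("line_id")


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()
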