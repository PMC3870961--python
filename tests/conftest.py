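import pytest

from flylinkage.design import build_line_designs
from flylinkage.table4 import load_table4


@pytest.fixture(scope="session")
def designs():
    return build_line_designs()

@pytest.fixture(scope="session")
def designs_by_name(designs):
    return {d.name: d for d in designs}


@pytest.fixture(scope="session")
def table4_summary():
    return load_table4()
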