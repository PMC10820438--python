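import pytest

from hfbscan.synthetic import generate_proteome


@pytest.fixture(scope="session")
def census():
    """The shipped census proteome (plan seed 42) with its truth table."""
    records, truth = generate_proteome()
    return records, truth
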