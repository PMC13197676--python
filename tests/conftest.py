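import pytest

from covfrag import crossassay


@pytest.fixture(scope="session")
def reactivity_records():
    """Library records from the bundled result tables (no benchmarks)."""
    return crossassay.records_from_table(crossassay.load_reactivity_table())


@pytest.fixture(scope="session")
def screen_table():
    return crossassay.load_screen_table()
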