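import pytest

from msapquant import (
    build_weight_table,
    characteristics,
    event_totals,
    load_triticale_dataset,
)


@pytest.fixture(scope="session")
def weight_table():
    return build_weight_table()


@pytest.fixture(scope="session")
def triticale():
    """(code counts, sample -> group) for the packaged triticale dataset."""
    return load_triticale_dataset()


@pytest.fixture(scope="session")
def triticale_totals(triticale, weight_table):
    counts, _ = triticale
    return event_totals(counts, weight_table)


@pytest.fixture(scope="session")
def triticale_characteristics(triticale_totals):
    return characteristics(triticale_totals)
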