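import pytest

from alliumtox import published


@pytest.fixture(scope="session")
def table_single():
    """Printed single-treatment endpoint table (12 rows)."""
    return published.load_cytogenetic_table("single")


@pytest.fixture(scope="session")
def table_combined():
    """Printed co-treatment endpoint table (10 rows incl. controls)."""
    return published.load_cytogenetic_table("combined")


@pytest.fixture(scope="session")
def band_matrices():
    """All four bundled primer band matrices, keyed by primer name."""
    return {p: published.load_band_matrix(p) for p in published.PRIMERS}


@pytest.fixture(scope="session")
def printed_polymorphism():
    return published.load_printed_polymorphism()
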