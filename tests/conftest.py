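import pandas as pd
import pytest

from claimsbirth import builtin_algorithms, default_codesets
from claimsbirth.months import month_index


@pytest.fixture(scope="session")
def cs():
    return default_codesets()


@pytest.fixture(scope="session")
def specs():
    return builtin_algorithms()


@pytest.fixture(scope="session")
def spec_by_id(specs):
    return {s.id: s for s in specs}


def make_claims(rows):
    """rows: (woman_id, month_idx, domain, code, suspected) tuples."""
    return pd.DataFrame(
        rows, columns=["woman_id", "month_idx", "domain", "code", "suspected"]
    )


def make_population(rows):
    """rows: (woman_id, birth_month_idx, husband_identified) tuples."""
    df = pd.DataFrame(rows, columns=["woman_id", "birth_month_idx", "husband_identified"])
    return df.set_index("woman_id")


def make_links(rows):
    """rows: (mother_id, child_birth_month_idx) tuples."""
    return pd.DataFrame(rows, columns=["mother_id", "child_birth_month_idx"])


@pytest.fixture(scope="session")
def window():
    return (month_index(2014, 4), month_index(2023, 2))
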