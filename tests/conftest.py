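import io

import numpy as np
import pytest

from mipscreen import datasets


@pytest.fixture(scope="session")
def stoich_table():
    """The packaged 35-protein doublet stoichiometry table."""
    return datasets.load_doublet_stoichiometry()


@pytest.fixture(scope="session")
def stoich_triples(stoich_table):
    """(id, MW, AQV) triples for the 35-protein ranking."""
    return [
        (r.name, float(r.mw_kda), float(r.aqv))
        for r in stoich_table.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def missing_table():
    """The packaged FAP52-knockout completely-missing protein table."""
    return datasets.load_fap52ko_missing()


@pytest.fixture(scope="session")
def missing_records():
    return datasets.fap52ko_missing_diff_records()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def fasta(text: str) -> io.StringIO:
    return io.StringIO(text)
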