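import random

import pytest

from cyclomine import tables

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def reference_rows():
    """The 86 bundled precursor rows as a DataFrame."""
    return tables.reference_precursors()


@pytest.fixture(scope="session")
def detected_rows():
    """The 13 MS-confirmed peptides with printed m/z columns."""
    return tables.detected_peptides()


@pytest.fixture()
def random_peptides():
    """Seeded random peptide sequences (length 2-12) for oracle checks."""
    rng = random.Random(20210311)

    def make(n, lo=2, hi=12):
        return ["".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(lo, hi)))
                for _ in range(n)]

    return make
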