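import pytest

from dopedlib import DopedDesign, GLUCAGON
from dopedlib.io import load_engineered_peptides, load_phage_peptides


@pytest.fixture(scope="session")
def reference_design() -> DopedDesign:
    """The published doped design: 9 randomized positions, 45% wt doping,
    18 alternatives, 6e7 physical clones."""
    return DopedDesign(parent=GLUCAGON,
                       randomized_positions=tuple(range(1, 10)),
                       p_wt=0.45, n_alternatives=18,
                       library_size=60_000_000)


@pytest.fixture(scope="session")
def phage_peptides():
    """The packaged 35-peptide activity table: (records, raw frame)."""
    return load_phage_peptides()


@pytest.fixture(scope="session")
def engineered_peptides():
    return load_engineered_peptides()
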