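import pathlib

import pytest

from markushgen.chemio import read_sdf
from markushgen.taxonomy import Taxonomy

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tax():
    return Taxonomy.default()


@pytest.fixture(scope="session")
def etheramine_series():
    """Committed 4-analog benzhydryl ether-amine series (para-halo x N-alkyl)."""
    return read_sdf(DATA / "etheramine_series.sdf")


@pytest.fixture(scope="session")
def library_compounds():
    return read_sdf(DATA / "library_compounds.sdf")


@pytest.fixture(scope="session")
def library_scaffolds():
    return read_sdf(DATA / "library_scaffolds.sdf")


@pytest.fixture()
def data_dir():
    return DATA
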