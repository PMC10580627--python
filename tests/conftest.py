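import pytest

from generank.fixtures import load_paper_fixtures


@pytest.fixture(scope="session")
def bundle():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def rubric(bundle):
    return bundle.rubric


@pytest.fixture(scope="session")
def repertoire(bundle):
    return bundle.repertoire


@pytest.fixture(scope="session")
def gpx4_line(bundle):
    return bundle.gpx4_record_line


@pytest.fixture(scope="session")
def m92(bundle):
    return bundle.repertoire.modules["M9.2"]


@pytest.fixture(scope="session")
def top5():
    return ("BCL2L1", "ALAS2", "SLC4A1", "CA1", "FECH")
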