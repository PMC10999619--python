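import pytest
from hypothesis import settings

from nichecomm import QuadratRecord, load_species_table_fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def rec(stage, quadrat, species, height=10.0, cover=0.2, abundance=2, transect="T1", site="site1"):
    return QuadratRecord(
        site_id=site,
        transect_id=transect,
        stage=stage,
        quadrat_id=quadrat,
        species=species,
        height=height,
        cover=cover,
        abundance=abundance,
    )


@pytest.fixture(scope="session")
def species_table():
    return load_species_table_fixture()


@pytest.fixture
def toy_records():
    """Two species over three S1 quadrats with known metrics.

    Species A: height 20, cover 0.4, in all 3 quadrats (f = 1).
    Species B: height 10, cover 0.1, in quadrats Q1, Q2 only (f = 2/3).
    """
    rows = []
    for q in ("Q1", "Q2", "Q3"):
        rows.append(rec("S1", q, "Aus alba", height=20.0, cover=0.4, abundance=2))
    for q in ("Q1", "Q2"):
        rows.append(rec("S1", q, "Bus bela", height=10.0, cover=0.1, abundance=1))
    return rows
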