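import pytest
from hypothesis import strategies as st

from ystr import (
    PANEL,
    AlleleSet,
    Haplotype,
    Population,
    get_fixture_population,
    get_fixture_signature,
)


@pytest.fixture(scope="session")
def obrien():
    return get_fixture_population("obrien")


@pytest.fixture(scope="session")
def irish():
    return get_fixture_population("irish")


@pytest.fixture(scope="session")
def control():
    return get_fixture_population("control")


@pytest.fixture(scope="session")
def dal_riata():
    return get_fixture_signature("dal_riata")


@pytest.fixture(scope="session")
def obrien_footprint():
    return get_fixture_signature("obrien_footprint")


# ---- hypothesis strategies -------------------------------------------------

alleles = st.one_of(
    st.integers(min_value=8, max_value=35),
    st.integers(min_value=8, max_value=35).map(lambda n: f"{n}.2"),
)


def allele_sets(locus: str):
    n = 2 if locus == "DYS385" else 1
    return st.lists(alleles, min_size=n, max_size=n).map(AlleleSet)


@st.composite
def haplotypes(draw, sample_id: str | None = None):
    locus_values = {loc: draw(allele_sets(loc)) for loc in PANEL}
    sid = sample_id or draw(st.text(
        alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=8
    ))
    metadata = draw(st.dictionaries(
        st.sampled_from(["surname_group", "ethnicity", "birthplace"]),
        st.text(alphabet="abcdefghijklmnopqrstuvwxyz ", min_size=1, max_size=12)
        .map(str.strip).filter(bool),
        max_size=2,
    ))
    return Haplotype(sid, locus_values, metadata)


@st.composite
def populations(draw, min_size: int = 0, max_size: int = 5):
    n = draw(st.integers(min_value=min_size, max_value=max_size))
    members = [draw(haplotypes(sample_id=f"S{i + 1}")) for i in range(n)]
    return Population(name="synthetic", members=members)
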