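import pytest

from duplexspectra import duplexsim, refio, signatures


@pytest.fixture(scope="session")
def region6382():
    """Synthetic 6382-nt reporter target used across the suite."""
    return duplexsim.synthetic_reference(seed=101)


@pytest.fixture(scope="session")
def composition6382(region6382):
    return refio.trinucleotide_composition(region6382)


@pytest.fixture(scope="session")
def sbs11_spectrum():
    return signatures.sbs11_like()


@pytest.fixture(scope="session")
def cpg_spectrum():
    return signatures.cpg_control()


@pytest.fixture
def small_region():
    return refio.ReferenceRegion(name="mini", sequence="ACGTACGGTACCGTAGCATG")
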