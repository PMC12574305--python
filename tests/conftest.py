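import pytest

from amore.fixtures import DOCTEST_SMILES, FixtureSpec, generate_smiles_set


@pytest.fixture(scope="session")
def standard_records():
    """The standard synthetic molecule set (n=100, seed=1)."""
    return generate_smiles_set(FixtureSpec(n_molecules=100, seed=1))


@pytest.fixture(scope="session")
def small_records():
    return generate_smiles_set(FixtureSpec(n_molecules=20, seed=7))


@pytest.fixture(scope="session")
def handful_smiles():
    """Small embedded list of common molecules."""
    return list(DOCTEST_SMILES)
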