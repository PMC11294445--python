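import pytest

from wolbkit import simulate


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated strain set shared by read-only tests."""
    return simulate.simulate_dataset(
        seed=7, n_strains=6, n_clades=2, n_core=40, n_accessory=15,
        n_reads=60, protein_length=160,
    )


@pytest.fixture(scope="session")
def small_tree():
    return simulate.sample_strain_tree(6, 2, seed=7)
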