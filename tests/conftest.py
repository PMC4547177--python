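import pytest

from panmatrix import make_toy_dataset


@pytest.fixture(scope="session")
def clean_toy():
    """Noise-free toy data: 5 core families + 1 orphan per genome, 3 genomes."""
    return make_toy_dataset(seed=7, n_genomes=3, n_core=5, n_orphan_per_genome=1)


@pytest.fixture(scope="session")
def noisy_toy():
    """Toy data with inversions, truncations and block splits planted."""
    return make_toy_dataset(
        seed=11,
        n_genomes=4,
        n_core=6,
        n_orphan_per_genome=1,
        n_dispensable=2,
        inversion_rate=0.4,
        truncation_rate=0.4,
        block_split_rate=0.4,
    )


@pytest.fixture(scope="session")
def clean_toy_dir(clean_toy, tmp_path_factory):
    d = tmp_path_factory.mktemp("clean_toy")
    return clean_toy, clean_toy.write(d)


@pytest.fixture(scope="session")
def noisy_toy_dir(noisy_toy, tmp_path_factory):
    d = tmp_path_factory.mktemp("noisy_toy")
    return noisy_toy, noisy_toy.write(d)
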