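import pytest

from vhsecleave import classifier, corpus, simulate


@pytest.fixture(scope="session")
def small_config():
    """A compact planted-rule corpus: fast, but signal-bearing."""
    return simulate.SimulationConfig(
        n_proteins=12, protein_length=200, n_ligands=400, seed=7
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    proteome = simulate.generate_proteome(small_config)
    ligands, truth = simulate.plant_cleavages(proteome, small_config)
    return proteome, ligands, truth


@pytest.fixture(scope="session")
def small_samples(small_config, small_corpus):
    proteome, ligands, _ = small_corpus
    return corpus.build_sample_set(proteome, ligands, half_width=10)


@pytest.fixture(scope="session")
def small_features(small_samples):
    return classifier.featurize(small_samples)


@pytest.fixture(scope="session")
def small_linear_model(small_features):
    return classifier.train(small_features, kernel="linear", C=1.0)
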