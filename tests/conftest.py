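import numpy as np
import pytest

from pudi.simulate import SyntheticParams, generate_synthetic_study

TOY_PARAMS = SyntheticParams(
    n_genes=80,
    n_positives=16,
    contamination=0.25,
    n_terms_per_ns=20,
    n_disease_terms=5,
    n_domains=20,
    n_disease_domains=5,
    mean_annotations=4.0,
    ppi_mean_degree=5.0,
)


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory):
    """Small synthetic study shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("toy_study")
    return generate_synthetic_study(TOY_PARAMS, seed=7, out_dir=str(out))


@pytest.fixture(scope="session")
def toy_config(toy_study):
    from pudi.experiments import study_config_for

    return study_config_for(toy_study, seed=7, folds=3, q_neighbors=5)


@pytest.fixture(scope="session")
def toy_data(toy_config):
    from pudi.pipeline import load_study

    return load_study(toy_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
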