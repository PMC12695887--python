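import numpy as np
import pytest
from hypothesis import settings

import pafingerprint as pf
from pafingerprint.prototype import TrainConfig, split_dataset, train

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rbc_templates():
    return pf.default_templates("rbc_species")


@pytest.fixture(scope="session")
def sheep_template(rbc_templates):
    return next(t for t in rbc_templates if t.name == "sheep")


@pytest.fixture(scope="session")
def default_config():
    return pf.AcquisitionConfig(seed=1)


@pytest.fixture(scope="session")
def rbc_dataset(rbc_templates, default_config):
    """Default 5-class washed-cell dataset: 40 signals per species."""
    return pf.generate_dataset(rbc_templates, 40, default_config)


@pytest.fixture(scope="session")
def rbc_classifier(rbc_dataset):
    """Default prototype-learning CNN trained on the 80% split."""
    return train(rbc_dataset, train_config=TrainConfig(seed=1))


@pytest.fixture(scope="session")
def rbc_split(rbc_dataset):
    tc = TrainConfig(seed=1)
    return split_dataset(rbc_dataset, tc.train_fraction, tc.stratified, tc.seed)


@pytest.fixture(scope="session")
def small_model_config():
    """A fast extractor for unit tests."""
    return pf.ModelConfig(
        input_length=128, conv_kernels=((5, 8), (3, 8)), pool_width=4,
        feature_dim=8, seed=0,
    )


def make_two_class_set(n_per_class=12, seed=0):
    """Two spectrally well-separated classes (for convergence tests)."""
    a = pf.SpeciesTemplate(
        "alpha",
        (pf.SpectralComponent(2.0e6, 1.0, 5e-6),),
        amplitude_jitter=0.05, frequency_jitter=0.001,
    )
    b = pf.SpeciesTemplate(
        "beta",
        (pf.SpectralComponent(7.0e6, 1.0, 5e-6),),
        amplitude_jitter=0.05, frequency_jitter=0.001,
    )
    cfg = pf.AcquisitionConfig(seed=seed)
    return pf.generate_dataset([a, b], n_per_class, cfg)


@pytest.fixture(scope="session")
def two_class_set():
    return make_two_class_set()
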