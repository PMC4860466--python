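import numpy as np
import pytest

from bilexmap import (
    LetterTable,
    PhonemeTable,
    SynthConfig,
    TrainingConfig,
    generate_dataset,
    train_model,
)


@pytest.fixture(scope="session")
def phoneme_table():
    return PhonemeTable.load()


@pytest.fixture(scope="session")
def letter_table():
    return LetterTable.load()


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled naming-norm generator config for fast unit tests."""
    return SynthConfig(
        n_objects=12, n_features=16, categories=(2, 2), n_names=(6, 5),
        participants=12, divergence=0.3, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, _ = generate_dataset(small_config)
    return dataset


@pytest.fixture(scope="session")
def tiny_model(small_dataset, phoneme_table, letter_table):
    """A short bilingual training run on the small dataset (50 epochs)."""
    config = TrainingConfig.scaled(50, condition="bilingual", n_replicates=1)
    return train_model(small_dataset, config, seed=3,
                       phoneme_table=phoneme_table, letter_table=letter_table)


@pytest.fixture(scope="session")
def tiny_model_no_lateral(small_dataset, phoneme_table, letter_table):
    config = TrainingConfig.scaled(50, condition="bilingual",
                                   ablation="no_lateral", n_replicates=1)
    return train_model(small_dataset, config, seed=3,
                       phoneme_table=phoneme_table, letter_table=letter_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
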