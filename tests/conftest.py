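import numpy as np
import pytest

from printfid import classifier as clf
from printfid import synthgen as sg


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """80 synthetic prints from the good/poor quality mixture, fixed seed."""
    images, manifest, matrix = sg.generate_labeled_dataset(80, seed=11)
    dataset = clf.make_labeled_dataset(images, manifest)
    return dataset, manifest, matrix


@pytest.fixture(scope="session")
def quick_config():
    """Reduced-size training configuration for fast classifier studies."""
    return clf.TrainingConfig(
        width=8,
        initial_dataset=40,
        batch_increment=40,
        max_epochs=3,
        early_stopping_patience=2,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
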