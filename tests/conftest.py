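import numpy as np
import pytest

from poprep.neurogen import TuningConfig, simulate_population
from poprep.stimgen import StimulusConfig, generate_stimulus_set


SMALL_COMPOSITION = dict(
    n_twin_pairs=11, n_cars=2, n_faces=2, n_silhouettes=2,
    n_textures=2, n_blank=1, n_low_contrast=2,
)


@pytest.fixture(scope="session")
def small_stimset():
    """33-image set with the same structure as the full composition."""
    return generate_stimulus_set(StimulusConfig(**SMALL_COMPOSITION), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_stimset):
    """Responses of 20 heterogeneously tuned neurons to the small set."""
    tuning = TuningConfig.random(n_neurons=20, seed=5, repetitions=7)
    return simulate_population(small_stimset, tuning, seed=6)


def random_dissimilarity(n: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.random((n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
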