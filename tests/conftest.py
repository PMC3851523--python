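import numpy as np
import pytest

from specsample import GenerativeParams, SpectralCountMatrix, simulate


@pytest.fixture
def toy_matrix():
    """3 preys x 2 bait purifications with a spread of count magnitudes."""
    return SpectralCountMatrix(
        prey_ids=["A", "B", "C"],
        experiment_ids=["e1", "e2"],
        counts=np.array([[3, 1], [1, 0], [0, 12]]),
        bait_of={"e1": "X", "e2": "Y"},
        is_control={"e1": False, "e2": False},
    )


SMALL_PARAMS = GenerativeParams(
    n_proteins=30,
    n_complexes=5,
    complex_size=3,
    n_experiments=15,
    baits_per_complex=2,
    contaminant_rate=3.0,
    seed=3,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study shared by tests that need realistic structure."""
    return simulate(SMALL_PARAMS)
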