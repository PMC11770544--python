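import numpy as np
import pytest
from hypothesis import settings

from larakit import AlignmentParams, SequenceSimSpec, simulate_family_sequences
from larakit.simulate import FAMILIES

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> AlignmentParams:
    return AlignmentParams()


@pytest.fixture(scope="session")
def clean_family_records():
    """Five noise-free records per family, keyed by family name."""
    return {
        family: simulate_family_sequences(
            SequenceSimSpec(family=family, n_sequences=5, seed=11)
        )
        for family in FAMILIES
    }


@pytest.fixture(scope="session")
def blosum_scorer(params):
    """Substitution scorer matching the package's configured matrix."""
    from larakit.alignment import _matrix_with_neutral_x

    matrix = _matrix_with_neutral_x(params.substitution_matrix)

    def score(x: str, y: str) -> float:
        return float(matrix[x, y])

    return score


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20882088)
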