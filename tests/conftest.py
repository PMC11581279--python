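import numpy as np
import pytest

from ecsurv.codebook import VariableCodebook, Variable, default_codebook
from ecsurv.cohort import Cohort


@pytest.fixture(scope="session")
def codebook13() -> VariableCodebook:
    return default_codebook()


@pytest.fixture
def toy_codebook() -> VariableCodebook:
    return VariableCodebook(
        (
            Variable("a", ("a0", "a1", "a2")),
            Variable("b", ("b0", "b1")),
            Variable("c", ("c0", "c1", "c2")),
        )
    )


def make_random_cohort(codebook, n, seed, death_rate=0.4):
    """Uniform random levels with a random determinate outcome."""
    rng = np.random.default_rng(seed)
    levels = np.column_stack(
        [rng.integers(0, v.n_levels, size=n) for v in codebook]
    )
    events = (rng.random(n) < death_rate).astype(np.int64)
    months = np.where(events == 1, rng.integers(1, 61, size=n), 60)
    return Cohort(codebook, levels, months, events)


@pytest.fixture
def random_toy_cohort(toy_codebook) -> Cohort:
    return make_random_cohort(toy_codebook, 200, seed=42)
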