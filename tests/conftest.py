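import numpy as np
import pytest

from triarm import Margin, RateTriple, TrialCounts
from triarm.model import constrained_loglik


@pytest.fixture
def dyspepsia_counts() -> TrialCounts:
    """Adverse-event counts from the functional-dyspepsia trial:
    simethicone (test) 12/58, cisapride (reference) 10/59, placebo 7/61."""
    return TrialCounts(12, 58, 10, 59, 7, 61)


@pytest.fixture
def theta06() -> Margin:
    return Margin(0.6)


@pytest.fixture
def theta08() -> Margin:
    return Margin(0.8)


def constrained_grid_max(counts: TrialCounts, margin: Margin, n_grid: int = 501):
    """Brute-force maximiser of the psi = 0 constrained kernel over the
    nuisance triangle {0 <= pi_P <= pi_R <= 1}; the independent oracle for
    restricted-MLE checks."""
    axis = np.linspace(0.0, 1.0, n_grid)
    A, B = np.meshgrid(axis, axis, indexing="ij")
    vals = np.where(A <= B, constrained_loglik(A, B, counts, margin), -np.inf)
    k = np.unravel_index(np.argmax(vals), vals.shape)
    return float(axis[k[0]]), float(axis[k[1]]), float(vals[k])


def random_counts(rng: np.random.Generator, n_max: int = 30) -> TrialCounts:
    ns = rng.integers(1, n_max + 1, size=3)
    xs = [int(rng.integers(0, n + 1)) for n in ns]
    return TrialCounts(xs[0], int(ns[0]), xs[1], int(ns[1]), xs[2], int(ns[2]))
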