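import numpy as np
import pytest

from raopart.diversity import AbundanceTable
from raopart.phylo import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def random_table(rng):
    """10 plots x 8 species, strictly positive row sums, some zeros."""
    values = rng.gamma(1.0, 5.0, size=(10, 8))
    values[rng.random(values.shape) < 0.3] = 0.0
    values[:, 0] += 1.0  # guarantee positive totals
    plots = [f"plot_{i}" for i in range(10)]
    species = [f"sp{j}" for j in range(8)]
    return AbundanceTable(plots, species, values)


def naive_rao(p, d):
    """Independent O(S^2) loop implementation of Rao's quadratic entropy."""
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += d[i, j] * p[i] * p[j]
    return q
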