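"""Shared fixtures: small graphs with known community structure and a
generated synthetic extract reused across modules."""

from itertools import combinations

import numpy as np
import pytest

from lcnet.cohort import apply_exclusions, derive_index, window_events
from lcnet.synth import GeneratorConfig, generate_population


def graph(edges, n):
    """Dense symmetric weight matrix from an (a, b[, weight]) edge list."""
    w = np.zeros((n, n))
    for a, b, *rest in edges:
        w[a, b] = w[b, a] = rest[0] if rest else 1.0
    return w


@pytest.fixture(scope="session")
def two_triangle():
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge edge (2,5).
    The triangle partition is the unique modularity maximum, Q = 5/14."""
    return graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 5)], 6)


@pytest.fixture(scope="session")
def disconnected_cliques():
    """Two disjoint triangles; the components are the obvious communities."""
    return graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)], 6)


def set_partitions(items):
    """All set partitions of a list (exhaustive-search oracle helper)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_q(w, modularity_fn):
    """Maximum modularity over every partition, by brute enumeration."""
    n = w.shape[0]
    best = -2.0
    for part in set_partitions(list(range(n))):
        lab = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            lab[list(block)] = c
        best = max(best, modularity_fn(w, lab))
    return best


def planted_two_block(seed, n_per_block=15, p_in=0.5, p_out=0.05):
    """Random 2-block graph with known block membership."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    w = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p = p_in if (i < n_per_block) == (j < n_per_block) else p_out
        if rng.random() < p:
            w[i, j] = w[j, i] = 1.0
    truth = [0] * n_per_block + [1] * n_per_block
    return w, truth


@pytest.fixture(scope="session")
def small_extract():
    """A 1,200-patient synthetic extract with the default planted subtypes."""
    return generate_population(GeneratorConfig(n_patients=1200, seed=42))


@pytest.fixture(scope="session")
def small_cohort(small_extract):
    tabs = small_extract
    index = derive_index(tabs.coded_events)
    return apply_exclusions(tabs.persons, tabs.visits, index, tabs.tests)


@pytest.fixture(scope="session")
def small_windowed(small_extract, small_cohort):
    return window_events(small_cohort, small_extract.coded_events, 60)
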