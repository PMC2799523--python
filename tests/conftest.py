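import numpy as np
import pytest

import restgraph as rg


@pytest.fixture(scope="session")
def region_table():
    return rg.load_region_table()


@pytest.fixture(scope="session")
def labels(region_table):
    return tuple(region_table["abbreviation"])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (6 vs 6 subjects) for fast end-to-end checks."""
    cfg = rg.CohortConfig(n_group_a=6, n_group_b=6, seed=11)
    return rg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort_matrices(labels):
    """Preprocessed per-subject correlation matrices of one full cohort."""
    cohort = rg.simulate_cohort(rg.CohortConfig(seed=5))
    mats = {"a": [], "b": []}
    for s in cohort.subjects:
        ts = rg.preprocess_subject(s)
        mats[s.group].append(rg.correlation_matrix(ts, labels=labels, tag=s.subject_id))
    return cohort, mats


def random_graph(rng: np.random.Generator, n: int, p: float) -> rg.BinaryGraph:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return rg.BinaryGraph(a | a.T)
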