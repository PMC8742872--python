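import numpy as np
import pandas as pd
import pytest

from cageshift.model import CtssMatrix, SampleSheet
from cageshift.simulate import SimConfig, simulate_ctss_experiment


@pytest.fixture
def samples12():
    return [f"{s}_{x}{r}" for s in "AB" for x in "mf" for r in (1, 2, 3)]


@pytest.fixture
def sheet12(samples12):
    return SampleSheet(pd.DataFrame({
        "sample_id": samples12,
        "strain": [s.split("_")[0] for s in samples12],
    }))


@pytest.fixture
def small_matrix(samples12):
    rng = np.random.default_rng(42)
    entries = {}
    for i in range(30):
        pos = 100 + 7 * i
        entries[("chr1", pos, "+")] = rng.poisson(5, len(samples12))
    return CtssMatrix.from_entries(entries, samples12)


@pytest.fixture(scope="session")
def sim_experiment():
    """Mid-size simulated experiment with planted effects, shared across tests."""
    cfg = SimConfig(seed=11, n_genes=20, n_alt_genes=3, n_shift_promoters=3,
                    n_ase_variants=5, n_null_ase_variants=5)
    return cfg, simulate_ctss_experiment(cfg)


def union_find_components(n_items, connected):
    """Brute-force transitive closure: connected(i, j) -> components as frozensets."""
    parent = list(range(n_items))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_items):
        for j in range(i + 1, n_items):
            if connected(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n_items):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}
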