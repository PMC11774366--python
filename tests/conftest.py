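"""Shared fixtures and independent brute-force oracles for the test suite."""

import numpy as np
import pytest

import maupbym as m


# ---------------------------------------------------------------------------
# oracles (deliberately naive implementations, independent of the package)
# ---------------------------------------------------------------------------


def moran_oracle(x, weights_dense, row_standardise):
    """O(n^2) double-loop Moran's I on a dense weight matrix."""
    w = np.array(weights_dense, dtype=float)
    if row_standardise:
        for i in range(w.shape[0]):
            s = w[i].sum()
            if s > 0:
                w[i] = w[i] / s
    x = np.asarray(x, float)
    n = x.size
    zbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - zbar) * (x[j] - zbar)
            s0 += w[i, j]
    den = sum((xi - zbar) ** 2 for xi in x)
    return n / s0 * num / den


def grid_edges(rows, cols, ids, queen=True):
    """Hand-enumerated grid contiguity edge list."""
    edges = []
    steps = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if queen else [])
    for r in range(rows):
        for c in range(cols):
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    edges.append((ids[r * cols + c], ids[rr * cols + cc]))
    return edges


def random_adjacency(n, rng, p_edge=0.3):
    """Random symmetric graph (guaranteed at least one edge)."""
    ids = [f"a{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((ids[i], ids[j]))
    if not edges:
        edges = [(ids[0], ids[1])]
    return m.build_adjacency(ids, edge_list=edges)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_hierarchy():
    """Two parents over four children over ... a hand-checkable 3-level tree.

    children c0..c3 with per-age populations; parents P0 = {c0, c1},
    P1 = {c2, c3}; one root R.
    """
    pop = np.array([[200.0, 100.0], [50.0, 50.0], [80.0, 20.0], [10.0, 40.0]])
    membership = {
        ("child", "parent"): {"c0": "P0", "c1": "P0", "c2": "P1", "c3": "P1"},
        ("parent", "root"): {"P0": "R", "P1": "R"},
    }
    return m.AreaHierarchy.from_finest(
        ["child", "parent", "root"], ["c0", "c1", "c2", "c3"], pop, membership
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A 4-level desk scenario reused across read-only tests."""
    cfg = m.ScenarioConfig(
        nesting=(256, 64, 16, 4), seed=11, level_names=("m", "s1", "s2", "s3")
    )
    return m.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def default_scenario():
    """The default-scale scenario (4096-area finest level, 64-area native)."""
    return m.simulate_scenario(m.ScenarioConfig(seed=23))


@pytest.fixture(scope="session")
def fitted_chain(small_scenario):
    """One short covariate fit at the 64-area level, shared across tests."""
    data = small_scenario
    lv = "s1"
    keep = data.outcomes[lv].E > 0
    outcome = data.outcomes[lv].subset(keep)
    adj = data.adjacency[lv].subset(keep)
    cov = data.covariates[lv].subset(keep)
    cfg = m.BYMConfig(n_iter=4000, n_burnin=1000, thin=3, seed=99)
    chain = m.fit_bym(outcome, cov, adj, cfg)
    return outcome, cov, adj, chain
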