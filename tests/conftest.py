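import numpy as np
import pytest

import comfnet as cn


@pytest.fixture(scope="session")
def toy_forward():
    """Shared toy lead field (64 channels, 190 sources) + mapped atlas."""
    return cn.generate_toy_leadfield(64, 190, seed=7)


@pytest.fixture(scope="session")
def atlas():
    return cn.load_aal95()


@pytest.fixture(scope="session")
def small_graphs():
    """Every connected graph on 3..6 nodes from the graph atlas, as
    (unit-weight adjacency, random-weight adjacency) pairs."""
    import networkx as nx

    rng = np.random.default_rng(99)
    pairs = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if not 3 <= n <= 6 or g.number_of_edges() == 0 or not nx.is_connected(g):
            continue
        unit = nx.to_numpy_array(g)
        weighted = unit * 0.0
        for i, j in g.edges():
            w = float(rng.uniform(0.2, 1.0))
            weighted[i, j] = weighted[j, i] = w
        pairs.append((unit, weighted))
    return pairs


@pytest.fixture(scope="session")
def beta_plv_matrix():
    """One generator-derived PLV matrix (ground-truth phases, beta band)."""
    spec = cn.CohortSpec(n_subjects=2, coupling_within=0.6,
                         active_regions=tuple(range(15)), n_epochs=6, seed=21)
    phases = cn.synthetic.generate_cohort_phases(spec)
    return cn.plv_from_phases(phases[0])
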