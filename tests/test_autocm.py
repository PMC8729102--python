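"""Auto-contractive map training, distances, MST and semantic maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pcosmet.autocm import (
    AutoCM,
    AutoCMResults,
    INIT_FRACTION,
    SCMGraph,
    minimum_spanning_tree,
    train_autocm,
    weights_to_distances,
)


@pytest.fixture(scope="module")
def binary_data():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, size=(200, 8)).astype(float)
    X[:, 3] = X[:, 2]  # planted duplicate pair
    return X


@pytest.fixture(scope="module")
def trained(binary_data):
    return train_autocm(binary_data)


def test_rejects_out_of_range_input():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        AutoCM(np.array([[0.0, 1.5], [0.2, 0.3]]))


def test_duplicated_columns_are_maximal_association(trained):
    W = trained.W
    row = W[2].copy()
    row[2] = -np.inf
    assert np.argmax(row) == 3


def test_zero_column_stays_at_initialization(binary_data):
    X = binary_data.copy()
    X[:, 5] = 0.0
    res = train_autocm(X)
    init = INIT_FRACTION * res.C
    assert res.v[5] == pytest.approx(init)
    assert np.allclose(res.W[5], init)
    assert np.allclose(res.W[:, 5], init)


def test_v_saturates_to_c_for_active_columns():
    X = np.ones((10, 2))
    res = train_autocm(X, C=2.0, max_epochs=20000, tol=0.0)
    assert np.all(res.v / res.C > 0.999)
    # monotone approach toward C before numerical saturation
    X3 = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    model = AutoCM(X3, C=2.0)
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            partial = [model.fit(max_epochs=k, tol=0.0).v[0] for k in (3, 8, 20)]
    assert partial[0] < partial[1] < partial[2] <= 2.0


def test_training_is_deterministic(binary_data, trained):
    again = train_autocm(binary_data)
    assert np.array_equal(again.W, trained.W)
    assert np.array_equal(again.v, trained.v)


def test_energy_non_increasing_after_burn_in(trained):
    diffs = np.diff(trained.energy_path[10:])
    assert np.all(diffs <= 1e-12)


def test_association_fidelity(binary_data, trained):
    """Distances shrink with co-occurrence frequency."""
    n = len(binary_data)
    f = (binary_data.T @ binary_data) / n
    d = trained.distances().to_numpy()
    iu = np.triu_indices(d.shape[0], k=1)
    rho = spearmanr(d[iu], 1.0 - f[iu]).statistic
    assert rho > 0


def _manual_results(W, C):
    N = W.shape[0]
    model = AutoCM(np.zeros((2, N)), C=C)
    return AutoCMResults(
        model=model, v=np.zeros(N), W=W, C=C, n_epochs=1,
        energy_path=np.array([0.0]), converged=True,
    )


def test_distance_formula_and_monotonicity():
    C = 4.0
    W = np.full((3, 3), 1.0)
    W[0, 1] = W[1, 0] = C  # maximal association
    res = _manual_results(W, C)
    d = res.distances().to_numpy()
    assert d[0, 1] == 0.0
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
    W2 = W.copy()
    W2[0, 2] += 0.5
    d2 = _manual_results(W2, C).distances().to_numpy()
    assert d2[0, 2] < d[0, 2]


def test_degenerate_rescale_warns():
    W = np.full((3, 3), 2.0)
    res = _manual_results(W, 4.0)
    with pytest.warns(UserWarning, match="degenerate"):
        d = res.distances(rescale=True).to_numpy()
    off = ~np.eye(3, dtype=bool)
    assert np.all(d[off] == 0.5)


def test_untrained_model_errors():
    res = _manual_results(np.zeros((2, 2)), 2.0)
    res.n_epochs = 0
    with pytest.raises(ValueError, match="untrained"):
        res.distances()


# ---------------------------------------------------------------------------
# Minimum spanning tree
# ---------------------------------------------------------------------------

def test_mst_triangle():
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    tree = minimum_spanning_tree(d)
    assert sorted(tree) == [(0, 1, 1.0), (1, 2, 2.0)]


def test_mst_returns_existing_tree():
    inf = np.inf
    d = np.array([
        [0.0, 1.0, inf, inf],
        [1.0, 0.0, 2.0, 3.0],
        [inf, 2.0, 0.0, inf],
        [inf, 3.0, inf, 0.0],
    ])
    tree = minimum_spanning_tree(d)
    assert sorted(tree) == [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 3.0)]


def test_mst_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        minimum_spanning_tree(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        minimum_spanning_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    with pytest.raises(ValueError, match="disconnected"):
        minimum_spanning_tree(np.array([
            [0.0, 1.0, np.inf], [1.0, 0.0, np.inf], [np.inf, np.inf, 0.0],
        ]))


def test_mst_deterministic_tie_break():
    d = np.ones((4, 4)) - np.eye(4)
    tree = minimum_spanning_tree(d)
    assert tree == [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]


# ---------------------------------------------------------------------------
# Semantic map
# ---------------------------------------------------------------------------

def test_chain_priorities():
    edges = [(0, 1, 0.5), (1, 2, 0.7)]
    scm = SCMGraph.from_edges(["RESPONDER", "A", "B"], edges, pole="RESPONDER")
    assert scm.pole_priorities[0] == ("A", 1, 0.5)
    assert scm.pole_priorities[1] == ("B", 2, pytest.approx(1.2))
    assert scm.priority_rank("A") == 0


def test_row_permutation_gives_identical_scm(binary_data):
    rng = np.random.default_rng(3)
    names = [f"N{j}" for j in range(binary_data.shape[1])]
    res1 = AutoCM(binary_data, node_names=names).fit()
    res2 = AutoCM(binary_data[rng.permutation(len(binary_data))], node_names=names).fit()
    scm1 = res1.semantic_map("N0")
    scm2 = res2.semantic_map("N0")
    assert sorted(scm1.graph.edges) == sorted(scm2.graph.edges)
    assert [n for n, _, _ in scm1.pole_priorities] == [n for n, _, _ in scm2.pole_priorities]


def test_scm_exports(tmp_path, trained):
    scm = trained.semantic_map(trained.node_names[0])
    scm.to_graphml(tmp_path / "scm.graphml")
    scm.to_dot(tmp_path / "scm.dot")
    payload = scm.priorities_json(tmp_path / "prio.json")
    assert (tmp_path / "scm.graphml").exists()
    assert "priorities" in payload
    assert "graph SCM" in (tmp_path / "scm.dot").read_text()


def test_summary_mentions_convergence(trained):
    text = trained.summary()
    assert "converged:   True" in text
    assert "strongest associations" in text
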