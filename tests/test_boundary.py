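"""Seam finding: gradients, cost construction, and the DP minimiser vs an
independent shortest-path oracle."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsirow.boundary import (
    BoundaryPath,
    cost_edge,
    cost_edge_with_shape,
    cost_grass_boundary,
    min_cost_path,
    shape_function_from_edge,
    vertical_gradient,
)


def oracle_min_cost(C: np.ndarray, lam: float):
    """Dijkstra over the explicit DAG of seam moves: the independent oracle."""
    H, W = C.shape
    G = nx.DiGraph()
    for y in range(H):
        G.add_edge("s", (0, y), weight=float(C[y, 0]))
        G.add_edge((W - 1, y), "t", weight=0.0)
    for x in range(W - 1):
        for y in range(H):
            for dy in (-1, 0, 1):
                y2 = y + dy
                if 0 <= y2 < H:
                    G.add_edge((x, y), (x + 1, y2),
                               weight=float(C[y2, x + 1]) + (lam if dy else 0.0))
    return nx.dijkstra_path_length(G, "s", "t")


# --- gradients ---------------------------------------------------------------


def test_gradient_of_constant_image_is_zero():
    np.testing.assert_array_equal(vertical_gradient(np.full((5, 4), 3.0)), 0.0)


def test_gradient_of_downward_ramp_is_constant_one():
    img = np.tile(np.arange(6.0)[:, None], (1, 3))  # values = y
    np.testing.assert_allclose(vertical_gradient(img), 1.0)


def test_gradient_peaks_on_a_step_edge():
    img = np.zeros((8, 5))
    img[4:, :] = 1.0  # dark above, bright below
    g = vertical_gradient(img)
    brute = np.gradient(img, axis=0)
    np.testing.assert_allclose(g, brute / np.abs(brute).max())
    assert set(np.flatnonzero(np.abs(g[:, 0]) == 1.0)) == {3, 4}


def test_gradient_requires_two_rows():
    with pytest.raises(ValueError):
        vertical_gradient(np.ones((1, 4)))


# --- cost construction -------------------------------------------------------


def test_grass_cost_is_zero_where_gradient_is_one():
    img = np.tile(np.arange(5.0)[:, None], (1, 4))  # g_y = 1 everywhere
    C = cost_grass_boundary(img)
    col_mean = img.mean(axis=0)
    np.testing.assert_allclose(C, 0.0, atol=1e-12)
    assert col_mean.shape == (4,)


def test_grass_cost_matches_direct_formula(rng):
    img = rng.uniform(-1, 1, (6, 8))
    g = vertical_gradient(img)
    expected = np.exp(-img.mean(axis=0))[None, :] * (1 - g)
    np.testing.assert_allclose(cost_grass_boundary(img), expected)


def test_grass_cost_reduces_to_edge_cost_for_zero_column_means(rng):
    img = rng.uniform(-1, 1, (7, 5))
    img -= img.mean(axis=0, keepdims=True)  # zero column means
    np.testing.assert_allclose(cost_grass_boundary(img), cost_edge(img))


def test_edge_cost_of_constant_image_is_one():
    np.testing.assert_allclose(cost_edge(np.full((4, 4), 2.0)), 1.0)


def test_edge_cost_minimal_along_dark_above_bright_below_step():
    img = np.zeros((9, 6))
    img[5:, :] = 1.0
    C = cost_edge(img)
    seam = min_cost_path(C, lambda_ver=0.0)
    assert set(seam.y_at) <= {4, 5}  # the two step rows carry the max gradient


def test_shape_cost_with_zero_lambda_equals_edge_cost(rng):
    img = rng.uniform(0, 1, (5, 5))
    d = rng.uniform(0, 3, (5, 5))
    np.testing.assert_allclose(cost_edge_with_shape(img, d, 0.0), cost_edge(img))


def test_shape_cost_matches_direct_formula(rng):
    img = rng.uniform(0, 1, (6, 7))
    d = rng.uniform(0, 3, (6, 7))
    lam = 0.7
    np.testing.assert_allclose(cost_edge_with_shape(img, d, lam),
                               1 - vertical_gradient(img) + lam * d)


def test_flat_image_shape_penalty_routes_path_through_v_vertex():
    img = np.ones((10, 6))
    bottom = BoundaryPath(np.full(6, 8), 0.0)
    d = shape_function_from_edge(bottom, expected_width=5, height=10)
    seam = min_cost_path(cost_edge_with_shape(img, d, 1.0), lambda_ver=0.0)
    np.testing.assert_array_equal(seam.y_at, 3)  # 8 - 5


def test_shape_function_is_a_per_column_v():
    bottom = BoundaryPath(np.array([7, 8, 7]), 0.0)
    d = shape_function_from_edge(bottom, expected_width=3, height=10)
    expected_rows = bottom.y_at - 3
    for x, row in enumerate(expected_rows):
        assert d[row, x] == 0.0
        assert d[row - 1, x] == 1.0 and d[row + 1, x] == 1.0
        np.testing.assert_allclose(d[:, x], np.abs(np.arange(10) - row))


def test_shape_function_rejects_off_image_expectation():
    bottom = BoundaryPath(np.array([3, 3, 3]), 0.0)
    with pytest.raises(ValueError, match="above the image"):
        shape_function_from_edge(bottom, expected_width=10, height=8)


# --- DP minimiser ------------------------------------------------------------


def test_zero_cost_matrix_yields_a_straight_horizontal_path():
    seam = min_cost_path(np.zeros((7, 9)), lambda_ver=0.3)
    assert seam.total_cost == 0.0
    assert np.all(seam.y_at == seam.y_at[0])


def test_single_column_matrix_picks_the_minimum_row(rng):
    C = rng.uniform(0, 1, (8, 1))
    seam = min_cost_path(C, lambda_ver=0.5)
    assert seam.y_at[0] == np.argmin(C[:, 0])
    assert seam.total_cost == pytest.approx(C[:, 0].min())


@pytest.mark.parametrize("lam", [0.0, 0.1, 5.0])
def test_dp_total_cost_equals_dijkstra_oracle(rng, lam):
    for _ in range(10):
        C = rng.uniform(0, 1, (rng.integers(2, 11), rng.integers(2, 9)))
        seam = min_cost_path(C, lam)
        assert seam.total_cost == pytest.approx(oracle_min_cost(C, lam), abs=1e-9)


@given(seed=st.integers(0, 10_000), h=st.integers(1, 8), w=st.integers(1, 8),
       lam=st.sampled_from([0.0, 0.1, 1.0, 10.0]))
def test_dp_path_cost_is_consistent_and_continuous(seed, h, w, lam):
    """The returned path is continuous and its edge-sum equals total_cost."""
    C = np.random.default_rng(seed).uniform(0, 2, (h, w))
    seam = min_cost_path(C, lam)
    assert seam.y_at.size == w
    if w > 1:
        assert np.abs(np.diff(seam.y_at)).max() <= 1
    n_diag = int(np.count_nonzero(np.diff(seam.y_at))) if w > 1 else 0
    path_cost = C[seam.y_at, np.arange(w)].sum() + lam * n_diag
    assert seam.total_cost == pytest.approx(path_cost)


def test_vertical_moves_do_not_increase_with_lambda(rng):
    """Raising the vertical penalty never adds diagonal moves to the optimum."""
    for _ in range(10):
        C = rng.uniform(0, 1, (10, 10))
        diag_counts = [
            int(np.count_nonzero(np.diff(min_cost_path(C, lam).y_at)))
            for lam in (0.0, 0.1, 1.0, 10.0)
        ]
        assert diag_counts == sorted(diag_counts, reverse=True)


def test_tie_break_prefers_straight_moves_and_smallest_row():
    C = np.zeros((4, 3))
    seam = min_cost_path(C, lambda_ver=0.0)  # every path costs 0
    np.testing.assert_array_equal(seam.y_at, 0)


def test_path_continuity_enforced_by_constructor():
    with pytest.raises(ValueError, match="continuity"):
        BoundaryPath(np.array([0, 2, 3]), 0.0)
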