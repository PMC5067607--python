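"""Spring-network statics: topology, equilibrium solver, shape metrics."""

import numpy as np
import pytest

from activegel.spring_network import (
    ActivationGeometry,
    activate,
    build_grid,
    measure_shape,
    residual_force,
    solve_equilibrium,
    total_energy,
)
from conftest import dense_energy_minimum


@pytest.mark.parametrize("nx,ny,spacing,n_nodes,n_edges", [
    (3, 3, 1.0, 9, 18),
    (30, 30, 1.0, 900, 1800),
    (4, 3, 2.5, 12, 24),
])
def test_grid_topology(nx, ny, spacing, n_nodes, n_edges):
    net = build_grid(nx, ny, spacing)
    assert net.n_nodes == n_nodes
    assert net.n_edges == n_edges
    assert (net.node_degrees() == 4).all()
    # positions form the regular lattice at the requested pitch
    assert np.isclose(net.positions[1, 0] - net.positions[0, 0], spacing)
    assert (net.coefficients == net.k_weak).all()


def test_grid_rejects_degenerate_sizes():
    for nx, ny in [(2, 5), (5, 2), (1, 1)]:
        with pytest.raises(ValueError):
            build_grid(nx, ny, 1.0)
    with pytest.raises(ValueError):
        build_grid(5, 5, 0.0)


def test_activation_edge_count_square_block():
    """Both-endpoint activation of a half-width-10 square on a 30x30 grid
    selects exactly the interior 4-neighbour edges of a 21x21 node block."""
    net = build_grid(30, 30, 1.0)
    act = activate(net, ActivationGeometry("square", half_width=10.0), 0.13)
    # exhaustive enumeration oracle
    inside = ActivationGeometry("square", half_width=10.0).node_mask(net)
    expected = sum(inside[i] and inside[j] for i, j in net.edges)
    assert expected == 2 * 21 * 20
    assert act.activated.sum() == expected
    assert np.allclose(act.coefficients[act.activated], 1.0 / 0.13)
    assert np.allclose(act.coefficients[~act.activated], 1.0)


def test_activation_degenerate_cases():
    net = build_grid(20, 20, 1.0)
    tiny = ActivationGeometry("circle", radius=1e-6, center=(10.5, 10.5))
    with pytest.warns(UserWarning):
        act = activate(net, tiny, 0.5)
    assert act.activated.sum() == 0
    # K = 1: all coefficients equal, network unchanged up to labels
    act = activate(net, ActivationGeometry("circle", radius=5.0), 1.0)
    assert np.allclose(act.coefficients, net.k_weak)
    with pytest.raises(ValueError):
        activate(net, ActivationGeometry("circle", radius=5.0), 0.0)
    with pytest.raises(ValueError):
        activate(net, ActivationGeometry("circle", radius=5.0), 1.5)


def test_geometry_margin_enforced():
    net = build_grid(20, 20, 1.0)
    with pytest.raises(ValueError):
        ActivationGeometry("circle", radius=9.5).node_mask(net)


def test_uniform_network_is_equilibrium():
    problem = solve_equilibrium(build_grid(15, 11, 2.0))
    assert np.abs(problem.displacements).max() < 1e-12


def test_full_height_band_matches_1d_chain():
    """A full-height activated band reduces each row to a 1D periodic chain:
    uniform tension gives strong-spring spacing d_s = K * d_w with
    d_w = L / (M + m K)."""
    nx, ny, K = 40, 6, 0.25
    m = 10                                   # strong springs per row
    net = build_grid(nx, ny, 1.0)
    mask = np.zeros((ny, nx), dtype=bool)
    mask[:, 10:10 + m + 1] = True
    problem = solve_equilibrium(
        activate(net, ActivationGeometry("raster", mask=mask), K))
    xs = problem.x_fin[:nx, 0]               # first row
    d_w = nx / ((nx - m) + m * K)
    assert np.allclose(np.diff(xs[10:10 + m + 1]), K * d_w, atol=1e-9)
    weak_gaps = np.diff(xs[10 + m + 1:])     # interior weak gaps after band
    assert np.allclose(weak_gaps, d_w, atol=1e-9)


@pytest.mark.parametrize("shape,geometry", [
    ((5, 5), ActivationGeometry("circle", radius=1.5)),
    ((6, 6), ActivationGeometry("circle", radius=2.0)),
    ((7, 7), ActivationGeometry("square", half_width=2.0)),
    ((7, 6), ActivationGeometry("rectangle", half_length=2.0, half_width=1.0)),
    ((7, 7), ActivationGeometry("hollow_square", outer_half_width=2.0,
                                wall_thickness=1.0)),
])
def test_solver_matches_dense_energy_minimization(geometry, shape):
    """The sparse linear solve and a dense quadratic-energy minimization are
    independent routes to the same force-free state."""
    net = activate(build_grid(*shape, 1.0), geometry, 0.2)
    problem = solve_equilibrium(net)
    oracle = dense_energy_minimum(net)
    scale = np.abs(problem.displacements).max()
    assert scale > 0
    assert np.abs(problem.x_fin - oracle).max() < 1e-8 * max(scale, 1.0)


def test_residual_energy_and_symmetry(circle_equilibrium):
    problem, geo = circle_equilibrium
    net = problem.network
    assert residual_force(problem) < 1e-8 * net.coefficients.max() * net.spacing
    assert total_energy(net, problem.x_fin) < total_energy(net)
    # D4 symmetry of the displacement field about the cell centre:
    # x-mirror, y-mirror and the diagonal transpose generate the group
    u = problem.displacements.reshape(120, 120, 2)
    ux, uy = u[..., 0], u[..., 1]
    assert np.abs(ux + np.roll(ux[:, ::-1], 1, axis=1)).max() < 1e-9
    assert np.abs(uy + np.roll(uy[::-1, :], 1, axis=0)).max() < 1e-9
    assert np.abs(ux - uy.T).max() < 1e-9


def test_circle_contracts_shape_preserving(circle_equilibrium):
    """Circular activation contracts nearly uniformly: the per-node radius
    ratio has a small spread and matches the model's thermodynamic-limit
    ratio 2K/(1+K) up to finite-size bias."""
    problem, geo = circle_equilibrium
    m = measure_shape(problem, geo)
    K = 0.13
    assert 0 < m.radius_ratio <= 1
    assert abs(m.radius_ratio - 2 * K / (1 + K)) < 0.01
    assert m.boundary_radius_cv < 0.05
    assert m.inner_circularity_final is None
    assert m.concavity_scores is None


def test_radius_ratio_monotone_in_K():
    ratios = []
    geo = ActivationGeometry("circle", radius=5.0)
    for K in np.arange(0.05, 1.0001, 0.05):
        net = activate(build_grid(40, 40, 1.0), geo, float(K))
        m = measure_shape(solve_equilibrium(net), geo)
        ratios.append(m.radius_ratio)
    assert np.all(np.diff(ratios) > 0)
    assert abs(ratios[-1] - 1.0) < 1e-6     # K ~ 1: no contraction


def test_circle_ratio_converges_with_cell_size():
    """Finite-size bias of the circle contraction ratio decreases as the
    periodic cell grows relative to the circle (ratios 3, 6, 12), approaching
    the continuum value 2K/(1+K)."""
    K, r = 0.13, 10.0
    limit = 2 * K / (1 + K)
    errs = []
    geo = ActivationGeometry("circle", radius=r)
    for cell_ratio in (3, 6, 12):
        n = int(2 * r * cell_ratio)
        net = activate(build_grid(n, n, 1.0), geo, K)
        m = measure_shape(solve_equilibrium(net), geo)
        errs.append(abs(m.radius_ratio - limit))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.005


def test_square_concave_edges():
    geo = ActivationGeometry("square", half_width=10.0)
    net = activate(build_grid(60, 60, 1.0), geo, 0.13)
    m = measure_shape(solve_equilibrium(net), geo)
    assert m.concavity_scores is not None
    assert (m.concavity_scores > 0).all()


def test_hollow_square_inner_boundary_rounds():
    net = build_grid(60, 60, 1.0)
    thin = ActivationGeometry("hollow_square", outer_half_width=10.0,
                              wall_thickness=2.0)
    m = measure_shape(solve_equilibrium(activate(net, thin, 0.13)), thin)
    assert m.inner_circularity_final > m.inner_circularity_initial
    thick = ActivationGeometry("hollow_square", outer_half_width=10.0,
                               wall_thickness=5.0)
    m2 = measure_shape(solve_equilibrium(activate(net, thick, 0.13)), thick)
    assert m2.inner_circularity_final > m2.inner_circularity_initial
    assert (m2.concavity_scores > 0).all()
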