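"""Kirchhoff/Darcy flow solver: oracles, conservation, mechanism properties."""

import numpy as np
import pytest

from lcnflow import (
    Canaliculus,
    FlowProblem,
    HydraulicParameters,
    LCNNetwork,
    Node,
    NodeKind,
    assemble_conductances,
    build_incidence,
    compute_sources,
    default_boundary_nodes,
    funneling_comb,
    randomize_conductances,
    shielded_path,
    solve_flow,
    velocity_map,
)
from lcnflow.errors import SingularNetworkError, ValidationError

from conftest import random_connected_network


def dense_solve(net, sources, boundary_ids):
    """Independent dense full-rank oracle for the flow system."""
    A = build_incidence(net).toarray()
    C = np.diag(net.conductances)
    L = A.T @ C @ A
    boundary = np.isin(net.node_ids, list(boundary_ids))
    interior = ~boundary
    f = np.where(boundary, 0.0, sources)
    p = np.zeros(net.n_nodes)
    p[interior] = np.linalg.solve(L[np.ix_(interior, interior)], f[interior])
    dp = -(A @ p)  # drop along the edge orientation
    q = net.conductances * dp
    return p, q


def make_problem(rng, n_nodes, extra_edges=15, n_boundary=3):
    net = random_connected_network(rng, n_nodes, extra_edges, n_boundary)
    sources = rng.normal(size=n_nodes)
    return FlowProblem(net, sources, default_boundary_nodes(net))


class TestComputeSources:
    def test_compression_gives_positive_source(self):
        nodes = [Node(0, (0, 0, 0), pore_volume=10.0), Node(1, (5, 0, 0))]
        net = LCNNetwork.from_components(nodes, [])
        f = compute_sources(net, np.array([-1e-3, 0.0]), HydraulicParameters())
        assert f[0] == pytest.approx(0.01)
        assert f[1] == 0.0

    def test_zero_strain_rate_gives_zero_sources(self, small_experiment):
        net = small_experiment.network
        f = compute_sources(net, np.zeros(net.n_nodes), HydraulicParameters())
        assert not f.any()

    def test_half_volume_of_incident_canaliculi(self):
        """Junction of 4 + 6 µm canaliculi, A = 0.045 → V = 0.225 µm³."""
        nodes = [Node(0, (0, 0, 0)), Node(1, (4, 0, 0)), Node(2, (4 + 6, 0, 0))]
        edges = [Canaliculus(0, 0, 1, 4.0), Canaliculus(1, 1, 2, 6.0)]
        net = LCNNetwork.from_components(nodes, edges)
        # stored pore volumes are zero → recomputed from incident edges
        rate = -2e-3
        f = compute_sources(net, np.full(3, rate), HydraulicParameters())
        assert f[1] == pytest.approx(0.5 * (4 + 6) * 0.045 * abs(rate))


class TestConductances:
    def test_darcy_channel_formula(self):
        nodes = [Node(0, (0, 0, 0)), Node(1, (30, 0, 0))]
        net = LCNNetwork.from_components(nodes, [Canaliculus(0, 0, 1, 30.0)])
        assemble_conductances(net, HydraulicParameters())
        assert net.conductances[0] == pytest.approx(1e-7 * 0.045 / (1e-3 * 30.0))

    def test_halving_length_doubles_conductance(self):
        nodes = [Node(0, (0, 0, 0)), Node(1, (2, 0, 0)), Node(2, (3, 0, 0))]
        edges = [Canaliculus(0, 0, 1, 2.0), Canaliculus(1, 1, 2, 1.0)]
        net = LCNNetwork.from_components(nodes, edges)
        assemble_conductances(net, HydraulicParameters())
        assert net.conductances[1] == pytest.approx(2.0 * net.conductances[0])

    def test_randomize_cv_zero_is_identity_and_seeded(self):
        rng = np.random.default_rng(0)
        net = random_connected_network(rng, 30)
        base = net.conductances.copy()
        randomize_conductances(net, 0.0, seed=1)
        np.testing.assert_array_equal(net.conductances, base)
        randomize_conductances(net, 0.5, seed=1)
        once = net.conductances.copy()
        net.conductances = base.copy()
        randomize_conductances(net, 0.5, seed=1)
        np.testing.assert_array_equal(net.conductances, once)

    def test_lognormal_factors_have_unit_mean(self):
        """Monte-Carlo check of the mean-1 lognormal parameterization."""
        rng = np.random.default_rng(2)
        nodes = [Node(i, (float(i), 0, 0)) for i in range(100_001)]
        edges = [Canaliculus(j, j, j + 1, 1.0) for j in range(100_000)]
        net = LCNNetwork.from_components(nodes, edges)
        net.conductances = np.ones(net.n_edges)
        cv = 0.5
        randomize_conductances(net, cv, seed=9)
        factors = net.conductances
        se = cv / np.sqrt(len(factors))
        assert abs(factors.mean() - 1.0) < 3 * se


class TestSolveFlow:
    def test_two_node_hand_solution(self):
        nodes = [Node(0, (0, 0, 0)), Node(1, (1, 0, 0), NodeKind.SURFACE)]
        net = LCNNetwork.from_components(nodes, [Canaliculus(0, 0, 1, 1.0)])
        net.conductances = np.array([1.0])
        sol = solve_flow(FlowProblem(net, np.array([2.0, 0.0]), frozenset({1})))
        assert sol.edge_flow_rate[0] == pytest.approx(2.0)
        assert sol.node_pressure[0] == pytest.approx(2.0)
        assert sol.edge_velocity[0] == pytest.approx(2.0 / 0.045)

    def test_threefold_symmetric_split(self):
        nodes = [Node(0, (0, 0, 0))] + [
            Node(i, (np.cos(i), np.sin(i), 0), NodeKind.SURFACE) for i in (1, 2, 3)
        ]
        edges = [Canaliculus(j, 0, j + 1, 5.0) for j in range(3)]
        net = LCNNetwork.from_components(nodes, edges)
        net.conductances = np.full(3, 0.7)
        sol = solve_flow(
            FlowProblem(net, np.array([3.0, 0, 0, 0]), frozenset({1, 2, 3}))
        )
        np.testing.assert_allclose(sol.edge_flow_rate, 1.0, rtol=1e-12)

    def test_matches_dense_oracle_on_random_networks(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(5, 31))
            problem = make_problem(rng, n, extra_edges=int(rng.integers(0, 12)))
            sol = solve_flow(problem)
            p_ref, q_ref = dense_solve(
                problem.network, problem.node_sources, problem.boundary_nodes
            )
            scale = max(np.abs(p_ref).max(), 1e-30)
            np.testing.assert_allclose(sol.node_pressure, p_ref, atol=1e-8 * scale)
            qscale = max(np.abs(q_ref).max(), 1e-30)
            np.testing.assert_allclose(sol.edge_flow_rate, q_ref, atol=1e-8 * qscale)

    def test_conservation_at_boundary(self):
        rng = np.random.default_rng(123)
        problem = make_problem(rng, 200, extra_edges=100, n_boundary=5)
        sol = solve_flow(problem)
        interior = np.ones(problem.network.n_nodes, dtype=bool)
        interior[sol.boundary_rows] = False
        total_source = problem.node_sources[interior].sum()
        assert sol.total_boundary_outflux == pytest.approx(total_source, rel=1e-9)

    def test_linearity_in_sources_and_conductances(self):
        rng = np.random.default_rng(4)
        problem = make_problem(rng, 50)
        sol = solve_flow(problem)
        doubled = FlowProblem(
            problem.network, 2.0 * problem.node_sources, problem.boundary_nodes
        )
        sol2 = solve_flow(doubled)
        np.testing.assert_allclose(sol2.edge_velocity, 2 * sol.edge_velocity,
                                   rtol=1e-9)
        problem.network.conductances = problem.network.conductances * 3.0
        sol3 = solve_flow(problem)
        np.testing.assert_allclose(sol3.node_pressure, sol.node_pressure / 3.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(sol3.edge_flow_rate, sol.edge_flow_rate,
                                   rtol=1e-9, atol=1e-20)

    def test_zero_load_zero_flow(self):
        rng = np.random.default_rng(6)
        net = random_connected_network(rng, 40)
        sol = solve_flow(
            FlowProblem(net, np.zeros(net.n_nodes), default_boundary_nodes(net))
        )
        assert not sol.edge_velocity.any()
        assert not sol.node_pressure.any()

    def test_antisymmetric_sources_give_antisymmetric_pressures(self):
        """Mirror-symmetric path with ± sources about a grounded centre."""
        nodes = [
            Node(0, (-2, 0, 0)),
            Node(1, (-1, 0, 0)),
            Node(2, (0, 0, 0), NodeKind.SURFACE),
            Node(3, (1, 0, 0)),
            Node(4, (2, 0, 0)),
        ]
        edges = [Canaliculus(j, j, j + 1, 1.0) for j in range(4)]
        net = LCNNetwork.from_components(nodes, edges)
        net.conductances = np.ones(4)
        f = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
        sol = solve_flow(FlowProblem(net, f, frozenset({2})))
        np.testing.assert_allclose(
            sol.node_pressure, -sol.node_pressure[::-1], atol=1e-12
        )

    def test_component_without_boundary_raises(self):
        nodes = [
            Node(0, (0, 0, 0)),
            Node(1, (1, 0, 0), NodeKind.SURFACE),
            Node(2, (5, 0, 0)),
            Node(3, (6, 0, 0)),
        ]
        edges = [Canaliculus(0, 0, 1, 1.0), Canaliculus(1, 2, 3, 1.0)]
        net = LCNNetwork.from_components(nodes, edges)
        net.conductances = np.ones(2)
        with pytest.raises(SingularNetworkError):
            solve_flow(FlowProblem(net, np.zeros(4), frozenset({1})))

    def test_unset_conductances_rejected(self):
        nodes = [Node(0, (0, 0, 0)), Node(1, (1, 0, 0), NodeKind.SURFACE)]
        net = LCNNetwork.from_components(nodes, [Canaliculus(0, 0, 1, 1.0)])
        with pytest.raises(ValidationError):
            solve_flow(FlowProblem(net, np.zeros(2), frozenset({1})))


class TestMechanisms:
    def test_funneling_halving_outlets_doubles_mean_speed(self):
        """Fixed sources through fewer surface canaliculi flow faster."""
        sol10 = solve_flow(funneling_comb(n_sources=10, n_surface=10))
        sol5 = solve_flow(funneling_comb(n_sources=10, n_surface=5))
        surf10 = np.abs(sol10.edge_velocity[10:]).mean()
        surf5 = np.abs(sol5.edge_velocity[10:]).mean()
        assert surf5 == pytest.approx(2.0 * surf10, rel=1e-12)

    def test_vascular_sink_shields_surface(self):
        base = solve_flow(shielded_path(with_vascular=False))
        shielded = solve_flow(shielded_path(with_vascular=True))

        def surface_outflux(problem_sol, problem):
            net = problem.network
            surf_rows = np.flatnonzero(net.kinds == int(NodeKind.SURFACE))
            idx = {r: i for i, r in enumerate(problem_sol.boundary_rows)}
            return sum(problem_sol.boundary_outflux[idx[r]] for r in surf_rows)

        p0 = shielded_path(with_vascular=False)
        p1 = shielded_path(with_vascular=True)
        out_base = surface_outflux(base, p0)
        out_shielded = surface_outflux(shielded, p1)
        assert out_shielded < out_base
        assert out_base == pytest.approx(1.0, rel=1e-9)


class TestVelocityMap:
    def test_uniform_speed_gives_constant_map(self):
        nodes = [
            Node(0, (0, 0, 0)),
            Node(1, (16, 0, 0), NodeKind.SURFACE),
            Node(2, (0, 8, 8), NodeKind.SURFACE),
            Node(3, (16, 8, 8), NodeKind.SURFACE),
        ]
        edges = [Canaliculus(0, 0, 1, 16.0)]
        net = LCNNetwork.from_components(nodes, edges)
        net.conductances = np.ones(1)
        sol = solve_flow(
            FlowProblem(net, np.array([0.9, 0, 0, 0]), frozenset({1, 2, 3}))
        )
        vm = velocity_map(sol, net, 8.0)
        speed = abs(sol.edge_velocity[0])
        filled = vm.grid[vm.grid > 0]
        np.testing.assert_allclose(filled, speed, rtol=1e-12)

    def test_empty_cells_are_zero_and_two_edge_weighting(self):
        nodes = [
            Node(0, (0.0, 0.1, 0.1)),
            Node(1, (6.0, 0.1, 0.1)),
            Node(2, (6.0, 6.1, 0.1)),
            Node(3, (0.0, 15.9, 15.9)),
        ]
        edges = [Canaliculus(0, 0, 1, 6.0), Canaliculus(1, 1, 2, 6.0)]
        net = LCNNetwork.from_components(nodes, edges)
        sol_like = type("S", (), {})()
        from lcnflow import FlowSolution

        sol = FlowSolution(
            node_pressure=np.zeros(4),
            edge_pressure_drop=np.zeros(2),
            edge_flow_rate=np.zeros(2),
            edge_velocity=np.array([2.0, 4.0]),
            boundary_rows=np.empty(0, dtype=int),
            boundary_outflux=np.empty(0),
        )
        vm = velocity_map(sol, net, 8.0)
        # both edges lie in cell (0,0,0): length-weighted mean of 2 and 4
        assert vm.grid[0, 0, 0] == pytest.approx((2.0 * 6 + 4.0 * 6) / 12.0)
        assert vm.grid[0, 1, 1] == 0.0
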