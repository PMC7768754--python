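"""Shared fixtures: random hydraulic networks and small synthetic animals."""

from __future__ import annotations

import numpy as np
import pytest

from lcnflow import (
    Canaliculus,
    HydraulicParameters,
    LCNNetwork,
    Node,
    NodeKind,
    SyntheticSpec,
    assemble_conductances,
    synthetic_experiment,
)


def random_connected_network(
    rng: np.random.Generator,
    n_nodes: int,
    extra_edges: int = 10,
    n_boundary: int = 3,
) -> LCNNetwork:
    """Random spanning tree plus extra edges; positive conductances.

    The last ``n_boundary`` nodes are flagged as surface (pressure 0).
    """
    pos = rng.uniform(0.0, 100.0, size=(n_nodes, 3))
    nodes = [
        Node(
            i,
            pos[i],
            NodeKind.SURFACE if i >= n_nodes - n_boundary else NodeKind.JUNCTION,
            pore_volume=float(rng.uniform(0.1, 5.0)),
        )
        for i in range(n_nodes)
    ]
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append(Canaliculus(len(edges), j, i, float(rng.uniform(1.0, 30.0))))
    for _ in range(extra_edges):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        edges.append(
            Canaliculus(len(edges), int(a), int(b), float(rng.uniform(1.0, 30.0)))
        )
    net = LCNNetwork.from_components(nodes, edges)
    assemble_conductances(net, HydraulicParameters())
    # heterogeneous conductances exercise the solver beyond one scale
    net.conductances = net.conductances * rng.uniform(0.2, 5.0, size=net.n_edges)
    return net


def small_spec(seed: int) -> SyntheticSpec:
    """Desk-scale synthetic animal used for replicate studies."""
    return SyntheticSpec(
        seed=seed,
        outer_radius=100.0,
        inner_radius=70.0,
        slab_thickness=20.0,
        n_lacunae=40,
        n_vascular=3,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One solved synthetic animal shared by read-only tests."""
    return synthetic_experiment(small_spec(seed=7))


@pytest.fixture(scope="session")
def default_network():
    """Default-spec synthetic network and geometry (the larger annulus)."""
    from lcnflow import generate_network

    return generate_network(SyntheticSpec(seed=11))
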