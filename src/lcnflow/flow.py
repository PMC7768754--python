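"""Circuit-theory solver for load-induced fluid flow through the LCN.

The network is treated as a hydraulic circuit: conservation of fluid at
every node (Kirchhoff's first law) combined with Darcy's law in every
canaliculus gives a weighted graph-Laplacian system

    AᵀCA · p = f,      q = C·Δp,      v = q / A_cs,

where A is the directed edge–node incidence matrix, C the diagonal
matrix of edge conductances, f the per-node fluid source rates and p
the nodal pressures.  Δp is the pressure drop along each edge's
orientation (tail minus head), so a positive q is flow from high to
low pressure along the edge direction.  Surface and vascular nodes are hydraulic sinks at
reference pressure 0 (Dirichlet); each connected component must contain
at least one such boundary node for the system to be solvable.

A node under compression expels fluid: the source rate is the node's
pore volume times the negated volumetric strain rate, so compression
(negative strain rate) yields a positive source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .errors import SingularNetworkError, SolverError, ValidationError
from .morphometry import DensityMap, _clip_segment_to_cells, _grid_layout
from .network import LCNNetwork, NodeKind, build_incidence


@dataclass
class HydraulicParameters:
    """Effective hydraulic properties of a canaliculus.

    The fluid flows in the fibre-filled annulus between the osteocyte
    process and the canalicular wall; that geometry is collapsed into a
    single effective permeability ``effective_permeability`` (µm²)
    acting over the constant annulus cross-section ``cross_section_area``
    (µm²), with fluid viscosity in Pa·s (µm-based unit system:
    conductances come out in µm³·s⁻¹·Pa⁻¹).
    """

    cross_section_area: float = 0.045
    effective_permeability: float = 1e-7
    fluid_viscosity: float = 1e-3

    def __post_init__(self):
        if min(
            self.cross_section_area,
            self.effective_permeability,
            self.fluid_viscosity,
        ) <= 0:
            raise ValidationError("hydraulic parameters must be strictly positive")


@dataclass
class FlowProblem:
    network: LCNNetwork
    node_sources: np.ndarray  # f_i, µm³/s, aligned with node order
    boundary_nodes: frozenset  # node ids with prescribed pressure 0

    def __post_init__(self):
        self.node_sources = np.asarray(self.node_sources, dtype=float)
        if len(self.node_sources) != self.network.n_nodes:
            raise ValidationError(
                "node_sources length does not match number of nodes"
            )
        self.boundary_nodes = frozenset(int(i) for i in self.boundary_nodes)


@dataclass
class FlowSolution:
    node_pressure: np.ndarray  # Pa
    edge_pressure_drop: np.ndarray  # Pa
    edge_flow_rate: np.ndarray  # µm³/s
    edge_velocity: np.ndarray  # µm/s
    boundary_rows: np.ndarray  # node row indices of boundary nodes
    boundary_outflux: np.ndarray  # µm³/s absorbed at each boundary node

    @property
    def total_boundary_outflux(self) -> float:
        return float(self.boundary_outflux.sum())

    def write_csv(self, network: LCNNetwork, edge_path, node_path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "edge_id": network.edge_ids,
                "q_um3_per_s": self.edge_flow_rate,
                "v_um_per_s": self.edge_velocity,
                "dp_Pa": self.edge_pressure_drop,
            }
        ).to_csv(edge_path, index=False, float_format="%.17g")
        pd.DataFrame(
            {"node_id": network.node_ids, "p_Pa": self.node_pressure}
        ).to_csv(node_path, index=False, float_format="%.17g")


def node_pore_volumes(
    network: LCNNetwork, lacunar_volumes: np.ndarray | None = None
) -> np.ndarray:
    """Total pore volume V_i per node.

    V_i equals half the volume of all canaliculi meeting at node i
    (length × cross-section area) plus, for lacuna and vascular nodes,
    the body volume itself.  If ``lacunar_volumes`` is None the body
    volumes stored on the network (``pore_volumes`` minus any
    canalicular share already included) are assumed to be body-only.
    """
    half = network.canalicular_half_volumes()
    body = (
        np.asarray(lacunar_volumes, dtype=float)
        if lacunar_volumes is not None
        else network.pore_volumes
    )
    body = np.where(network.kind_mask(NodeKind.LACUNA, NodeKind.VASCULAR), body, 0.0)
    return half + body


def compute_sources(
    network: LCNNetwork,
    node_strain_rates: np.ndarray,
    params: HydraulicParameters,
    pore_volumes: np.ndarray | None = None,
) -> np.ndarray:
    """Per-node fluid source rate f_i = V_i · (−strain rate), µm³/s.

    Compression (negative volumetric strain rate) squeezes the pore
    space and expels fluid, giving a positive source.
    """
    rates = np.asarray(node_strain_rates, dtype=float)
    if len(rates) != network.n_nodes:
        raise ValidationError("strain-rate vector length does not match nodes")
    if pore_volumes is None:
        pore_volumes = network.pore_volumes
        half = network.canalicular_half_volumes()
        # stored volumes must already include the canalicular half-share
        if np.any(pore_volumes + 1e-9 * (1 + half) < half):
            pore_volumes = node_pore_volumes(network)
    return np.asarray(pore_volumes, dtype=float) * (-rates)


def assemble_conductances(
    network: LCNNetwork, params: HydraulicParameters
) -> LCNNetwork:
    """Set Darcy channel conductances C_jj = k_p · A / (µ · l_j) in place."""
    if network.n_edges and np.any(network.lengths <= 0):
        raise ValidationError("zero or negative canaliculus length")
    network.conductances = (
        params.effective_permeability
        * network.areas
        / (params.fluid_viscosity * network.lengths)
    )
    return network


def randomize_conductances(
    network: LCNNetwork, coefficient_of_variation: float, seed: int
) -> LCNNetwork:
    """Multiply conductances by i.i.d. lognormal factors with mean 1.

    Models random variability of canalicular permeabilities;
    ``coefficient_of_variation`` is the CV of the multiplicative factor.
    """
    cv = float(coefficient_of_variation)
    if not 0 <= cv < 2:
        raise ValidationError("coefficient_of_variation must be in [0, 2)")
    if cv == 0 or network.n_edges == 0:
        return network
    sigma2 = np.log1p(cv * cv)
    rng = np.random.default_rng(seed)
    factors = rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2),
                            size=network.n_edges)
    network.conductances = network.conductances * factors
    return network


def default_boundary_nodes(network: LCNNetwork) -> frozenset:
    """Surface and vascular nodes: the hydraulic sinks at pressure 0."""
    mask = network.kind_mask(NodeKind.SURFACE, NodeKind.VASCULAR)
    return frozenset(int(i) for i in network.node_ids[mask])


def solve_flow(problem: FlowProblem) -> FlowSolution:
    """Solve the Kirchhoff/Darcy system for pressures, flows, velocities."""
    net = problem.network
    n, m = net.n_nodes, net.n_edges
    if np.any(~np.isfinite(net.conductances)) or np.any(net.conductances <= 0):
        raise ValidationError(
            "edge conductances are unset; call assemble_conductances first"
        )
    A = build_incidence(net)
    C = sp.diags(net.conductances)
    boundary = np.zeros(n, dtype=bool)
    for i in problem.boundary_nodes:
        boundary[net.node_row(i)] = True

    # every connected component needs a boundary node
    adj = (A.T @ A).tocsr() if m else sp.csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    for c in range(n_comp):
        members = labels == c
        if not boundary[members].any():
            ids = net.node_ids[members][:5].tolist()
            raise SingularNetworkError(
                f"component {c} (nodes {ids}...) has no boundary node"
            )

    f = problem.node_sources.copy()
    f[boundary] = 0.0  # sinks absorb their own source contribution
    interior = ~boundary
    p = np.zeros(n)
    if interior.any() and m:
        L = (A.T @ C @ A).tocsr()
        Lii = L[interior][:, interior].tocsc()
        p_int = spla.spsolve(Lii, f[interior])
        p[interior] = p_int
    # pressure drop along the edge orientation (tail minus head): a
    # positive q means flow from high to low pressure along the edge
    dp = -(A @ p) if m else np.zeros(0)
    q = net.conductances * dp
    v = q / net.areas
    if not np.all(np.isfinite(p)):
        raise SolverError("non-finite pressures from sparse solve")

    inflow = A.T @ q if m else np.zeros(n)  # net flow converging on a node
    scale = max(np.abs(f).max() if n else 0.0, 1e-30)
    resid = np.abs(inflow[interior] + f[interior]).max() if interior.any() else 0.0
    if resid > 1e-9 * scale:
        raise SolverError(f"interior flux residual {resid:.3e} exceeds tolerance")

    boundary_rows = np.flatnonzero(boundary)
    outflux = inflow[boundary_rows]
    return FlowSolution(
        node_pressure=p,
        edge_pressure_drop=dp,
        edge_flow_rate=q,
        edge_velocity=v,
        boundary_rows=boundary_rows,
        boundary_outflux=outflux,
    )


def velocity_map(
    solution: FlowSolution,
    network: LCNNetwork,
    grid_edge: float = 8.0,
    depth_average: bool = False,
) -> DensityMap:
    """Length-weighted mean |v| of canalicular segments per grid cell.

    Cells containing no canaliculus are 0.  With ``depth_average`` the
    z-dimension is collapsed (length-weighted over the imaging depth)
    before the ratio is formed and a (nx, ny, 1) map is returned.
    """
    origin, shape = _grid_layout(network, grid_edge)
    num = np.zeros(shape)
    den = np.zeros(shape)
    rows = network.edge_rows()
    pos = network.positions
    speed = np.abs(solution.edge_velocity)
    for j, (a, b) in enumerate(rows):
        vj = speed[j]

        def accumulate(cell, length, _v=vj):
            num[cell] += _v * length
            den[cell] += length

        _clip_segment_to_cells(pos[a], pos[b], origin, grid_edge, shape, accumulate)
    if depth_average:
        num = num.sum(axis=2, keepdims=True)
        den = den.sum(axis=2, keepdims=True)
    grid = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return DensityMap(grid, grid_edge, origin.copy(), "velocity")
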