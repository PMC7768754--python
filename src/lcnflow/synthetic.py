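"""Synthetic LCN cross-sections, image stacks and (re)modeling responses.

The generator emulates the structure the analysis assumes: an annular
cortical cross-section filled with a jittered cubic lattice of
canaliculi, a bell-shaped heterogeneous canalicular density with a
depleted angular band, quasi-uniform lacunae, vascular channels
co-located with the low-density band, surface nodes on both boundaries
and a sine-wave-like angular remodeling response generated from the
flow predictor itself.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .flow import (
    FlowProblem,
    FlowSolution,
    HydraulicParameters,
    assemble_conductances,
    compute_sources,
    default_boundary_nodes,
    solve_flow,
)
from .geometry import SurfaceGeometry, circular_geometry
from .imaging import ImageStack
from .network import DEFAULT_CROSS_SECTION_AREA, LCNNetwork, NodeKind
from .predictor import (
    PredictorConfig,
    SurfaceProfile,
    WedgeAssignment,
    assign_wedges,
    flow_predictor,
    score_calibrated,
    strain_predictor,
    triangular_smooth,
)
from .strain import LoadingProtocol, beam_bending_field, sample_at_nodes


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cross-section.

    The default emulates a murine cortical cross-section at desk scale:
    a 50-µm slab of an annulus with target canalicular density
    0.27 µm/µm³, a depleted density band (low-density region of the
    cortex), ~150 lacunae and a few vascular channels inside the band.
    """

    seed: int = 0
    outer_radius: float = 150.0  # µm
    inner_radius: float = 100.0  # µm
    slab_thickness: float = 50.0  # µm
    target_ca_dn: float = 0.27  # µm/µm³
    # (angular position °, full width °, depletion factor in (0, 1])
    density_band: tuple = (120.0, 60.0, 0.2)
    n_lacunae: int = 150
    n_vascular: int = 6
    lacuna_volume: float = 200.0  # µm³
    vascular_volume: float = 2000.0  # µm³
    response_noise_sd: float = 5.0  # µm
    jitter: float = 0.25  # fraction of lattice spacing

    def __post_init__(self):
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValidationError("need 0 < inner_radius < outer_radius")
        if not 0 < self.density_band[2] <= 1:
            raise ValidationError("depletion factor must be in (0, 1]")

    @property
    def annulus_volume(self) -> float:
        return (
            math.pi
            * (self.outer_radius**2 - self.inner_radius**2)
            * self.slab_thickness
        )


def _band_factor(theta_deg: np.ndarray, band: tuple) -> np.ndarray:
    """Angular density modulation: 1 away from the band, `depletion` at centre."""
    angle, width, depletion = band
    sigma = max(width, 1e-9) / 2.355  # FWHM → SD
    d = np.abs((theta_deg - angle + 180.0) % 360.0 - 180.0)
    return 1.0 - (1.0 - depletion) * np.exp(-0.5 * (d / sigma) ** 2)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _build_lattice(spec: SyntheticSpec, spacing: float, rng: np.random.Generator):
    """Jittered cubic lattice restricted to the annular slab."""
    R, r = spec.outer_radius, spec.inner_radius
    nx = int(np.floor(2 * R / spacing)) + 1
    nzl = max(int(np.floor(spec.slab_thickness / spacing)) + 1, 2)
    ax = -R + (np.arange(nx) + 0.5) * spacing
    az = (np.arange(nzl) + 0.5) * spacing * (
        spec.slab_thickness / (nzl * spacing)
    )
    az = np.linspace(spacing / 2, spec.slab_thickness - spacing / 2, nzl)
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    rho = np.sqrt(X**2 + Y**2)
    inside = (rho >= r - spacing / 2) & (rho <= R + spacing / 2)
    lattice_index = -np.ones(inside.shape, dtype=np.int64)
    lattice_index[inside] = np.arange(int(inside.sum()))
    pts = np.column_stack([X[inside], Y[inside], Z[inside]])
    rho_in = rho[inside]
    surface = (rho_in <= r + spacing / 2) | (rho_in >= R - spacing / 2)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=pts.shape) * spacing
    pts = pts + jit
    edges = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = lattice_index[tuple(sl_a)].ravel()
        b = lattice_index[tuple(sl_b)].ravel()
        ok = (a >= 0) & (b >= 0)
        edges.append(np.column_stack([a[ok], b[ok]]))
    edges = np.vstack(edges)
    return pts, surface, edges


def _generate_once(spec: SyntheticSpec, spacing: float):
    rng = np.random.default_rng(spec.seed)
    pts, surface_mask, lattice_edges = _build_lattice(spec, spacing, rng)
    n = len(pts)
    if n < 8 or len(lattice_edges) == 0:
        raise ValidationError("infeasible spec: lattice too coarse for the annulus")

    mid = 0.5 * (pts[lattice_edges[:, 0]] + pts[lattice_edges[:, 1]])
    theta = np.degrees(np.arctan2(mid[:, 1], mid[:, 0])) % 360.0
    keep_p = _band_factor(theta, spec.density_band)
    kept = rng.uniform(size=len(lattice_edges)) < keep_p

    # reconnect: re-add dropped lattice edges that bridge components
    uf = _UnionFind(n)
    for a, b in lattice_edges[kept]:
        uf.union(int(a), int(b))
    dropped = np.flatnonzero(~kept)
    dropped = dropped[rng.permutation(len(dropped))]
    readd = []
    for j in dropped:
        a, b = lattice_edges[j]
        if uf.union(int(a), int(b)):
            readd.append(j)
    kept[readd] = True
    edges = lattice_edges[kept]

    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    kinds = np.where(surface_mask, int(NodeKind.SURFACE), int(NodeKind.JUNCTION))

    interior = np.flatnonzero(~surface_mask)
    if len(interior) < spec.n_lacunae + spec.n_vascular:
        raise ValidationError(
            "infeasible spec: fewer interior nodes than lacunae + vascular"
        )
    lac = rng.choice(interior, size=spec.n_lacunae, replace=False)
    kinds[lac] = int(NodeKind.LACUNA)

    # vascular channels sit inside the low-density band, mid-cortex
    band_angle, band_width, _ = spec.density_band
    theta_n = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    dang = np.abs((theta_n - band_angle + 180.0) % 360.0 - 180.0)
    rho_n = np.hypot(pts[:, 0], pts[:, 1])
    mid_r = 0.5 * (spec.inner_radius + spec.outer_radius)
    cand = np.flatnonzero(
        (~surface_mask)
        & (kinds != int(NodeKind.LACUNA))
        & (dang <= max(band_width, 20.0))
        & (np.abs(rho_n - mid_r) < 0.3 * (spec.outer_radius - spec.inner_radius))
    )
    if len(cand) < spec.n_vascular:
        cand = np.flatnonzero((~surface_mask) & (kinds != int(NodeKind.LACUNA)))
    vasc = rng.choice(cand, size=spec.n_vascular, replace=False)
    kinds[vasc] = int(NodeKind.VASCULAR)

    body = np.zeros(n)
    body[lac] = spec.lacuna_volume
    body[vasc] = spec.vascular_volume

    net = LCNNetwork(
        node_ids=np.arange(n),
        positions=pts,
        kinds=kinds,
        pore_volumes=body,
        edge_ids=np.arange(len(edges)),
        endpoints=edges,
        lengths=lengths,
        areas=np.full(len(edges), DEFAULT_CROSS_SECTION_AREA),
    )
    net.pore_volumes = body + net.canalicular_half_volumes()
    return net


def generate_network(spec: SyntheticSpec):
    """Generate a synthetic LCN and its cross-section geometry.

    The lattice spacing is calibrated so that the mean canalicular
    density over the annulus matches ``target_ca_dn``: an initial
    spacing is predicted from the band-modulated keep probability, the
    achieved density is measured on a first draw, and the network is
    regenerated once with the corrected spacing (same seed, so the
    result is a pure function of the spec).

    Returns ``(network, geometry)``.
    """
    band_mean = float(np.mean(_band_factor(np.linspace(0, 360, 721), spec.density_band)))
    spacing = math.sqrt(3.0 * band_mean / spec.target_ca_dn)
    if spacing > (spec.outer_radius - spec.inner_radius) / 2:
        raise ValidationError(
            "infeasible spec: target density too low for this annulus "
            f"(need spacing {spacing:.1f} µm in a "
            f"{spec.outer_radius - spec.inner_radius:.1f} µm cortex)"
        )
    net = _generate_once(spec, spacing)
    achieved = net.lengths.sum() / spec.annulus_volume
    ratio = achieved / spec.target_ca_dn
    if abs(ratio - 1) > 0.02:
        spacing *= math.sqrt(ratio)
        net = _generate_once(spec, spacing)
    geometry = circular_geometry(spec.inner_radius, spec.outer_radius)
    return net, geometry


# ---------------------------------------------------------------------
# Defined small synthetics for flow-mechanism properties
# ---------------------------------------------------------------------

def funneling_comb(
    n_sources: int = 10,
    n_surface: int = 10,
    source_rate: float = 1.0,
    params: HydraulicParameters | None = None,
) -> FlowProblem:
    """Comb-to-surface network: upstream sources drain through a collector
    into ``n_surface`` identical surface canaliculi.

    With fixed total source, the flow is funneled: the mean speed in the
    surface canaliculi scales as 1/n_surface.
    """
    from .network import Canaliculus, Node

    params = params or HydraulicParameters()
    nodes = [Node(0, (0.0, 0.0, 0.0), NodeKind.JUNCTION)]  # collector
    edges = []
    for i in range(n_sources):
        nid = 1 + i
        nodes.append(Node(nid, (-10.0, 2.0 * i, 0.0), NodeKind.JUNCTION))
        edges.append(Canaliculus(len(edges), nid, 0, length=10.0))
    for i in range(n_surface):
        nid = 1 + n_sources + i
        nodes.append(Node(nid, (10.0, 2.0 * i, 0.0), NodeKind.SURFACE))
        edges.append(Canaliculus(len(edges), 0, nid, length=10.0))
    net = LCNNetwork.from_components(nodes, edges)
    assemble_conductances(net, params)
    sources = np.zeros(net.n_nodes)
    sources[1 : 1 + n_sources] = source_rate
    return FlowProblem(net, sources, default_boundary_nodes(net))


def shielded_path(
    with_vascular: bool,
    source_rate: float = 1.0,
    params: HydraulicParameters | None = None,
) -> FlowProblem:
    """Source draining to a surface, optionally shielded by a vascular sink.

    A vascular channel inserted between the source and the surface
    offers a lower-resistance path and strictly reduces the flux that
    reaches the surface.
    """
    from .network import Canaliculus, Node

    params = params or HydraulicParameters()
    nodes = [
        Node(0, (0.0, 0.0, 0.0), NodeKind.JUNCTION),  # source
        Node(1, (10.0, 0.0, 0.0), NodeKind.JUNCTION),
        Node(2, (20.0, 0.0, 0.0), NodeKind.JUNCTION),
        Node(3, (30.0, 0.0, 0.0), NodeKind.SURFACE),
    ]
    edges = [
        Canaliculus(0, 0, 1, length=10.0),
        Canaliculus(1, 1, 2, length=10.0),
        Canaliculus(2, 2, 3, length=10.0),
    ]
    if with_vascular:
        nodes.append(Node(4, (10.0, 8.0, 0.0), NodeKind.VASCULAR, pore_volume=500.0))
        edges.append(Canaliculus(3, 1, 4, length=8.0))
    net = LCNNetwork.from_components(nodes, edges)
    assemble_conductances(net, params)
    sources = np.zeros(net.n_nodes)
    sources[0] = source_rate
    return FlowProblem(net, sources, default_boundary_nodes(net))


# ---------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------

def generate_image(
    network: LCNNetwork,
    voxel_size: float = 0.37,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = 3.0,
    background: float = 20.0,
    foreground: float = 200.0,
    lacuna_aspect: float = 1.0,
) -> ImageStack:
    """Rasterize a network as a confocal-like stack.

    Canaliculi become bright tubes about two voxels in diameter, lacunae
    become ellipsoids of matching body volume (``lacuna_aspect`` is the
    long/short axis ratio; 1 gives spheres), vascular channels thick
    z-spanning cylinders, all on a dark background with optional
    additive Gaussian noise.
    """
    box = network.bounding_box
    lo = box[0] - margin
    hi = box[1] + margin
    shape_xyz = np.ceil((hi - lo) / voxel_size).astype(int)
    nzyx = (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0]))
    img = np.full(nzyx, background, dtype=np.float32)

    def to_vox(p):
        return (np.asarray(p) - lo) / voxel_size - 0.5  # voxel-centre convention

    def stamp_ball(centre_vox, radius_vox):
        c = np.asarray(centre_vox, dtype=float)
        r = float(radius_vox)
        zlo = max(int(np.floor(c[2] - r)), 0)
        zhi = min(int(np.ceil(c[2] + r)) + 1, nzyx[0])
        ylo = max(int(np.floor(c[1] - r)), 0)
        yhi = min(int(np.ceil(c[1] + r)) + 1, nzyx[1])
        xlo = max(int(np.floor(c[0] - r)), 0)
        xhi = min(int(np.ceil(c[0] + r)) + 1, nzyx[2])
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            return
        Z, Y, X = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r
        img[zlo:zhi, ylo:yhi, xlo:xhi][inside] = foreground

    # canaliculi: tubes ~3 voxels across (2×2 beams degenerate under
    # 3D thinning, so the radius stays safely above one voxel)
    rows = network.edge_rows()
    half = network.canalicular_half_volumes()
    for a, b in rows:
        pa, pb = network.positions[a], network.positions[b]
        seg = pb - pa
        length = np.linalg.norm(seg)
        nstep = max(int(np.ceil(length / (voxel_size * 0.5))), 1)
        for t in np.linspace(0.0, 1.0, nstep + 1):
            stamp_ball(to_vox(pa + t * seg), 1.6)

    # lacunae: ellipsoids of the body volume
    for row in np.flatnonzero(network.kind_mask(NodeKind.LACUNA)):
        vol = max(float(network.pore_volumes[row] - half[row]), 1.0)
        asp = max(lacuna_aspect, 1.0)
        short = (3.0 * vol / (4.0 * math.pi * asp)) ** (1.0 / 3.0)
        axes = np.array([asp * short, short, short]) / voxel_size
        c = to_vox(network.positions[row])
        r_max = axes.max()
        zlo = max(int(np.floor(c[2] - r_max)), 0)
        zhi = min(int(np.ceil(c[2] + r_max)) + 1, nzyx[0])
        ylo = max(int(np.floor(c[1] - r_max)), 0)
        yhi = min(int(np.ceil(c[1] + r_max)) + 1, nzyx[1])
        xlo = max(int(np.floor(c[0] - r_max)), 0)
        xhi = min(int(np.ceil(c[0] + r_max)) + 1, nzyx[2])
        Z, Y, X = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        inside = (
            ((X - c[0]) / axes[0]) ** 2
            + ((Y - c[1]) / axes[1]) ** 2
            + ((Z - c[2]) / axes[2]) ** 2
            <= 1.0
        )
        img[zlo:zhi, ylo:yhi, xlo:xhi][inside] = foreground

    # vascular channels: thick cylinders spanning the slab (z)
    for row in np.flatnonzero(network.kind_mask(NodeKind.VASCULAR)):
        vol = max(float(network.pore_volumes[row] - half[row]), 1.0)
        height = (hi[2] - lo[2])
        radius = math.sqrt(vol / (math.pi * height)) / voxel_size
        c = to_vox(network.positions[row])
        Y, X = np.mgrid[0 : nzyx[1], 0 : nzyx[2]]
        disk = (X - c[0]) ** 2 + (Y - c[1]) ** 2 <= radius * radius
        img[:, disk] = foreground

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return ImageStack(img, voxel_size)


def phantom_network(box: float = 70.0) -> LCNNetwork:
    """Hand-built phantom: 1 vascular channel, 6 lacunae, 6 junctions,
    24 canaliculi — a ground truth for the image pipeline.

    Every canaliculus ends at a body or at a three-arm junction with
    well-separated arms, so a noise-free rasterization must skeletonize
    back to exactly this topology.
    """
    from .network import Canaliculus, Node

    c = box / 2.0
    nodes = [Node(0, (c, c, 11.0), NodeKind.VASCULAR, pore_volume=1500.0)]
    edges = []
    for i in range(6):
        ang = math.radians(60.0 * i)
        nodes.append(
            Node(
                1 + i,
                (c + 20.0 * math.cos(ang), c + 20.0 * math.sin(ang), 9.0),
                NodeKind.LACUNA,
                pore_volume=75.0,
            )
        )
    for i in range(6):
        ang = math.radians(60.0 * i)
        nodes.append(
            Node(
                7 + i,
                (c + 29.0 * math.cos(ang), c + 29.0 * math.sin(ang), 13.0),
                NodeKind.JUNCTION,
            )
        )

    def dist(i, j):
        return float(
            np.linalg.norm(
                np.asarray(nodes[i].position) - np.asarray(nodes[j].position)
            )
        )

    for i in range(6):  # lacuna ↔ vascular spokes
        edges.append(Canaliculus(len(edges), 1 + i, 0, dist(1 + i, 0)))
    for i in range(6):  # lacuna ↔ its radial junction
        edges.append(Canaliculus(len(edges), 1 + i, 7 + i, dist(1 + i, 7 + i)))
    for i in range(6):  # lacunar ring
        a, b = 1 + i, 1 + (i + 1) % 6
        edges.append(Canaliculus(len(edges), a, b, dist(a, b)))
    for i in range(6):  # outer junction ring
        a, b = 7 + i, 7 + (i + 1) % 6
        edges.append(Canaliculus(len(edges), a, b, dist(a, b)))
    return LCNNetwork.from_components(nodes, edges)


# ---------------------------------------------------------------------
# End-to-end synthetic experiment and response generation
# ---------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """Everything one synthetic animal produces."""

    spec: SyntheticSpec
    network: LCNNetwork
    geometry: SurfaceGeometry
    solution: FlowSolution
    assignment: WedgeAssignment
    strain_field: object
    measured: dict  # surface → SurfaceProfile (remodeling thickness, µm)
    true_slope: float
    true_intercept: float


def run_flow_pipeline(
    network: LCNNetwork,
    geometry: SurfaceGeometry,
    params: HydraulicParameters | None = None,
    protocol: LoadingProtocol | None = None,
    neutral_axis_angle: float = 105.0,
    asymmetry: float = 1.4,
):
    """Strain sources → flow solve → wedge assignment for one network."""
    params = params or HydraulicParameters()
    protocol = protocol or LoadingProtocol()
    assemble_conductances(network, params)
    field = beam_bending_field(geometry, protocol, neutral_axis_angle, asymmetry)
    rates = sample_at_nodes(field, network)
    sources = compute_sources(network, rates, params)
    problem = FlowProblem(network, sources, default_boundary_nodes(network))
    solution = solve_flow(problem)
    assignment = assign_wedges(network, geometry)
    return solution, assignment, field


def generate_response(
    network: LCNNetwork,
    geometry: SurfaceGeometry,
    solution: FlowSolution,
    assignment: WedgeAssignment,
    true_R: float = 15.0,
    slope: float | None = None,
    intercept: float | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    smoothing_window: float = 30.0,
):
    """Synthetic measured (re)modeling thickness per wedge and surface.

    measured = slope · (smoothed flow predictor at ``true_R``) +
    intercept + N(0, noise_sd), independently per wedge.  With
    ``slope``/``intercept`` unset they are scaled so the response spans
    about [−10, 50] µm, the magnitude of murine tibial (re)modeling.

    Returns ``(measured, slope, intercept)``.
    """
    cfg = PredictorConfig(decay_length=true_R, smoothing_window=smoothing_window)
    rng = np.random.default_rng(seed)
    smoothed = {
        s: triangular_smooth(
            flow_predictor(solution, assignment, cfg, s), smoothing_window
        )
        for s in ("endocortical", "periosteal")
    }
    if slope is None:
        span = max(max(np.ptp(p.values) for p in smoothed.values()), 1e-30)
        slope = 60.0 / span
    if intercept is None:
        lowest = min(p.values.min() for p in smoothed.values())
        intercept = -10.0 - slope * lowest
    measured = {}
    for s, p in smoothed.items():
        noise = rng.normal(0.0, noise_sd, size=p.wedge_count) if noise_sd > 0 else 0.0
        measured[s] = SurfaceProfile(
            slope * p.values + intercept + noise, s, "remodeling_thickness"
        )
    return measured, float(slope), float(intercept)


def synthetic_experiment(
    spec: SyntheticSpec,
    true_R: float = 15.0,
    params: HydraulicParameters | None = None,
    protocol: LoadingProtocol | None = None,
    neutral_axis_angle: float = 105.0,
    asymmetry: float = 1.4,
) -> SyntheticExperiment:
    """One synthetic animal: network, flow solution and measured response."""
    network, geometry = generate_network(spec)
    solution, assignment, field = run_flow_pipeline(
        network, geometry, params, protocol, neutral_axis_angle, asymmetry
    )
    measured, slope, intercept = generate_response(
        network,
        geometry,
        solution,
        assignment,
        true_R=true_R,
        noise_sd=spec.response_noise_sd,
        seed=spec.seed + 1,
    )
    return SyntheticExperiment(
        spec=spec,
        network=network,
        geometry=geometry,
        solution=solution,
        assignment=assignment,
        strain_field=field,
        measured=measured,
        true_slope=slope,
        true_intercept=intercept,
    )


def score_experiment(
    exp: SyntheticExperiment,
    decay_length: float = 15.0,
    window: float = 30.0,
    sampling_step: float = 2.0,
) -> dict:
    """Calibrated RMSE of the flow and the strain predictor on one animal.

    Returns ``{"flow": {...}, "strain": {...}}`` with slope, intercept
    and per-surface RMSE (µm) each, both predictors calibrated jointly
    over the two surfaces against the measured response.
    """
    cfg = PredictorConfig(
        decay_length=decay_length,
        smoothing_window=window,
        sampling_step=sampling_step,
    )
    surfaces = ("endocortical", "periosteal")
    flow_p = [
        triangular_smooth(
            flow_predictor(exp.solution, exp.assignment, cfg, s), window
        )
        for s in surfaces
    ]
    strain_p = [
        triangular_smooth(
            strain_predictor(
                exp.strain_field,
                exp.geometry,
                cfg,
                s,
                z=exp.spec.slab_thickness / 2.0,
            ),
            window,
        )
        for s in surfaces
    ]
    measured = [exp.measured[s] for s in surfaces]
    return {
        "flow": score_calibrated(flow_p, measured),
        "strain": score_calibrated(strain_p, measured),
    }
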