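"""Graph representation of the lacunocanalicular network (LCN).

The LCN is stored column-wise: node attributes (position, kind, pore
volume) and edge attributes (endpoints, length, cross-section area,
hydraulic conductance) live in parallel numpy arrays.  ``Node`` and
``Canaliculus`` are light record types used to build networks and to
inspect single elements; all heavy computation works on the arrays.

Units are micrometres throughout: positions in µm, lengths in µm,
areas in µm², volumes in µm³ and conductances in µm³·s⁻¹·Pa⁻¹.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import SchemaError, StructuralError, ValidationError

DEFAULT_CROSS_SECTION_AREA = 0.045
"""Cross-sectional area (µm²) of the annular fluid space of a canaliculus.

Confocal microscopy cannot resolve canalicular diameters, so a single
constant annulus area is imposed on every edge.
"""


class NodeKind(enum.IntEnum):
    """Role of a network node.

    * ``JUNCTION`` – intersection of canaliculi (or a canalicular
      endpoint at the border of the imaged volume).
    * ``LACUNA`` – osteocyte lacuna; carries the lacunar pore volume.
    * ``VASCULAR`` – vascular channel; hydraulic sink/source.
    * ``SURFACE`` – node on the endocortical or periosteal bone surface.
    """

    JUNCTION = 0
    LACUNA = 1
    VASCULAR = 2
    SURFACE = 3


_KIND_NAMES = {k.name.lower(): k for k in NodeKind}


def parse_kind(value) -> NodeKind:
    """Coerce a string/int into a :class:`NodeKind`, validating it."""
    if isinstance(value, NodeKind):
        return value
    if isinstance(value, (int, np.integer)):
        try:
            return NodeKind(int(value))
        except ValueError as exc:
            raise ValidationError(f"unknown node kind {value!r}") from exc
    name = str(value).strip().lower()
    if name not in _KIND_NAMES:
        raise ValidationError(f"unknown node kind {value!r}")
    return _KIND_NAMES[name]


@dataclass
class Node:
    """A single LCN node (junction, lacuna, vascular channel or surface)."""

    id: int
    position: Sequence[float]
    kind: NodeKind = NodeKind.JUNCTION
    pore_volume: float = 0.0


@dataclass
class Canaliculus:
    """A single canaliculus: a directed edge between two nodes.

    Orientation (``node_a`` → ``node_b``) fixes the sign of flow; it has
    no physical meaning beyond that.
    """

    id: int
    node_a: int
    node_b: int
    length: float
    cross_section_area: float = DEFAULT_CROSS_SECTION_AREA
    conductance: float = np.nan


class LCNNetwork:
    """Column-wise container for an LCN graph.

    Parameters are parallel arrays; rows of node arrays correspond to
    nodes (in a fixed order) and rows of edge arrays to canaliculi.
    Edge endpoints are given as node *ids*; an internal id → row map is
    maintained.
    """

    def __init__(
        self,
        node_ids,
        positions,
        kinds,
        pore_volumes,
        edge_ids,
        endpoints,
        lengths,
        areas=None,
        conductances=None,
        voxel_size: float | None = None,
    ):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.kinds = np.asarray(kinds, dtype=np.int8)
        self.pore_volumes = np.asarray(pore_volumes, dtype=float)
        self.edge_ids = np.asarray(edge_ids, dtype=np.int64)
        self.endpoints = np.asarray(endpoints, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(lengths, dtype=float)
        if areas is None:
            areas = np.full(len(self.edge_ids), DEFAULT_CROSS_SECTION_AREA)
        self.areas = np.asarray(areas, dtype=float)
        if conductances is None:
            conductances = np.full(len(self.edge_ids), np.nan)
        self.conductances = np.asarray(conductances, dtype=float)
        self.voxel_size = voxel_size
        self._index = {int(i): row for row, i in enumerate(self.node_ids)}
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_components(
        cls,
        nodes: Iterable[Node],
        edges: Iterable[Canaliculus],
        voxel_size: float | None = None,
    ) -> "LCNNetwork":
        nodes = list(nodes)
        edges = list(edges)
        return cls(
            node_ids=[n.id for n in nodes],
            positions=[np.asarray(n.position, dtype=float) for n in nodes]
            or np.empty((0, 3)),
            kinds=[parse_kind(n.kind) for n in nodes],
            pore_volumes=[n.pore_volume for n in nodes],
            edge_ids=[e.id for e in edges],
            endpoints=[(e.node_a, e.node_b) for e in edges] or np.empty((0, 2)),
            lengths=[e.length for e in edges],
            areas=[e.cross_section_area for e in edges] or None,
            conductances=[e.conductance for e in edges] or None,
            voxel_size=voxel_size,
        )

    @classmethod
    def empty(cls) -> "LCNNetwork":
        return cls.from_components([], [])

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    def node_row(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def edge_rows(self) -> np.ndarray:
        """Edge endpoints as (m, 2) node *row* indices."""
        if self.n_edges == 0:
            return np.empty((0, 2), dtype=np.int64)
        lookup = self._index
        return np.array(
            [(lookup[int(a)], lookup[int(b)]) for a, b in self.endpoints],
            dtype=np.int64,
        )

    @property
    def bounding_box(self) -> np.ndarray:
        """Axis-aligned extents ((xmin, ymin, zmin), (xmax, ymax, zmax)) in µm."""
        if self.n_nodes == 0:
            return np.zeros((2, 3))
        return np.vstack([self.positions.min(axis=0), self.positions.max(axis=0)])

    def edge_midpoints(self) -> np.ndarray:
        rows = self.edge_rows()
        if len(rows) == 0:
            return np.empty((0, 3))
        return 0.5 * (self.positions[rows[:, 0]] + self.positions[rows[:, 1]])

    def kind_mask(self, *kinds: NodeKind) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        for k in kinds:
            mask |= self.kinds == int(k)
        return mask

    def canalicular_half_volumes(self) -> np.ndarray:
        """Per-node half-sum of incident canalicular volumes (length × area)."""
        out = np.zeros(self.n_nodes)
        if self.n_edges:
            rows = self.edge_rows()
            half = 0.5 * self.lengths * self.areas
            np.add.at(out, rows[:, 0], half)
            np.add.at(out, rows[:, 1], half)
        return out

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if len(self._index) != self.n_nodes:
            dup = len(self.node_ids) - len(set(self.node_ids.tolist()))
            raise StructuralError(f"{dup} duplicate node id(s)")
        if len(set(self.edge_ids.tolist())) != self.n_edges:
            raise StructuralError("duplicate edge ids")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite node position")
        if np.any(self.pore_volumes < 0):
            raise ValidationError("negative pore volume")
        if self.n_edges:
            for eid, (a, b) in zip(self.edge_ids, self.endpoints):
                if int(a) not in self._index or int(b) not in self._index:
                    raise StructuralError(
                        f"edge {int(eid)} references missing node "
                        f"({int(a)}, {int(b)})"
                    )
                if int(a) == int(b):
                    raise StructuralError(f"edge {int(eid)} is a self-loop")
            if np.any(self.lengths <= 0):
                raise ValidationError("canaliculus length must be > 0")
            if np.any(self.areas <= 0):
                raise ValidationError("cross-section area must be > 0")


def build_incidence(network: LCNNetwork) -> sp.csr_matrix:
    """Directed edge–node incidence matrix A (edges × nodes).

    Row j has +1 at the node edge j points toward (``node_b``) and −1 at
    the node it points away from (``node_a``); row sums are zero.
    """
    m, n = network.n_edges, network.n_nodes
    if m == 0:
        return sp.csr_matrix((0, n))
    rows = network.edge_rows()
    data = np.tile([-1.0, 1.0], m)
    indices = rows.ravel()
    indptr = np.arange(0, 2 * m + 1, 2)
    return sp.csr_matrix((data, indices, indptr), shape=(m, n))


# ---------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------

_NODE_COLUMNS = ["node_id", "x_um", "y_um", "z_um", "kind", "pore_volume_um3"]
_EDGE_COLUMNS = ["edge_id", "node_a", "node_b", "length_um", "area_um2"]
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _csv_paths(path):
    """A CSV network is a pair of files derived from one base path."""
    import os

    base, ext = os.path.splitext(str(path))
    if ext.lower() == ".csv":
        path = base
    return f"{path}_nodes.csv", f"{path}_edges.csv"


def write_network(network: LCNNetwork, path, format: str = "graphml") -> None:
    """Write a network to GraphML or to a CSV node-table/edge-list pair."""
    import pandas as pd

    if format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for i in range(network.n_nodes):
            g.add_node(
                int(network.node_ids[i]),
                x_um=float(network.positions[i, 0]),
                y_um=float(network.positions[i, 1]),
                z_um=float(network.positions[i, 2]),
                kind=NodeKind(int(network.kinds[i])).name.lower(),
                pore_volume_um3=float(network.pore_volumes[i]),
            )
        for j in range(network.n_edges):
            a, b = (int(x) for x in network.endpoints[j])
            g.add_edge(
                a,
                b,
                edge_id=int(network.edge_ids[j]),
                length_um=float(network.lengths[j]),
                area_um2=float(network.areas[j]),
            )
        nx.write_graphml(g, str(path))
    elif format == "csv_edge_list":
        node_path, edge_path = _csv_paths(path)
        nodes = pd.DataFrame(
            {
                "node_id": network.node_ids,
                "x_um": network.positions[:, 0],
                "y_um": network.positions[:, 1],
                "z_um": network.positions[:, 2],
                "kind": [NodeKind(int(k)).name.lower() for k in network.kinds],
                "pore_volume_um3": network.pore_volumes,
            }
        )
        edges = pd.DataFrame(
            {
                "edge_id": network.edge_ids,
                "node_a": network.endpoints[:, 0],
                "node_b": network.endpoints[:, 1],
                "length_um": network.lengths,
                "area_um2": network.areas,
            }
        )
        nodes.to_csv(node_path, index=False, float_format=_FLOAT_FMT)
        edges.to_csv(edge_path, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> LCNNetwork:
    """Read a network written by :func:`write_network`."""
    import pandas as pd

    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(str(path), force_multigraph=True)
        node_attrs = {"x_um", "y_um", "z_um", "kind", "pore_volume_um3"}
        edge_attrs = {"edge_id", "length_um", "area_um2"}
        nodes, edges = [], []
        for nid, d in g.nodes(data=True):
            missing = node_attrs - set(d)
            if missing:
                raise SchemaError(
                    f"node {nid} missing attributes: {sorted(missing)}", missing
                )
            nodes.append(
                Node(
                    id=int(nid),
                    position=(d["x_um"], d["y_um"], d["z_um"]),
                    kind=parse_kind(d["kind"]),
                    pore_volume=float(d["pore_volume_um3"]),
                )
            )
        for a, b, d in g.edges(data=True):
            missing = edge_attrs - set(d)
            if missing:
                raise SchemaError(
                    f"edge ({a}, {b}) missing attributes: {sorted(missing)}", missing
                )
            edges.append(
                Canaliculus(
                    id=int(d["edge_id"]),
                    node_a=int(a),
                    node_b=int(b),
                    length=float(d["length_um"]),
                    cross_section_area=float(d["area_um2"]),
                )
            )
        nodes.sort(key=lambda n: n.id)
        edges.sort(key=lambda e: e.id)
        return LCNNetwork.from_components(nodes, edges)
    elif format == "csv_edge_list":
        node_path, edge_path = _csv_paths(path)
        nodes = pd.read_csv(node_path)
        edges = pd.read_csv(edge_path)
        missing = [c for c in _NODE_COLUMNS if c not in nodes.columns]
        missing += [c for c in _EDGE_COLUMNS if c not in edges.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}", missing)
        kinds = [parse_kind(k) for k in nodes["kind"]]
        return LCNNetwork(
            node_ids=nodes["node_id"].to_numpy(),
            positions=nodes[["x_um", "y_um", "z_um"]].to_numpy(),
            kinds=kinds,
            pore_volumes=nodes["pore_volume_um3"].to_numpy(),
            edge_ids=edges["edge_id"].to_numpy(),
            endpoints=edges[["node_a", "node_b"]].to_numpy(),
            lengths=edges["length_um"].to_numpy(),
            areas=edges["area_um2"].to_numpy(),
        )
    else:
        raise ValidationError(f"unknown network format {format!r}")
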