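"""Network morphometry on cubic subvolumes.

Canalicular density (Ca.Dn, µm/µm³) and pore density (µm³/µm³) are
evaluated on a regular grid of cubic subvolumes covering the network's
bounding box.  Canaliculi are clipped exactly at subvolume borders so
that the total length is conserved; lacunar/vascular pore volume is
distributed with an equivalent-volume sphere footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import LCNNetwork, NodeKind


@dataclass
class DensityMap:
    """Scalar density on a grid of cubic subvolumes.

    ``grid[ix, iy, iz]`` covers the cube with corner
    ``origin + (ix, iy, iz) * subvolume_edge``.
    """

    grid: np.ndarray
    subvolume_edge: float
    origin: np.ndarray
    quantity: str  # "canalicular_density" | "pore_density" | "velocity"

    @property
    def cell_volume(self) -> float:
        return self.subvolume_edge**3

    def total(self) -> float:
        """Sum over cells times cell volume (total length or volume)."""
        return float(self.grid.sum() * self.cell_volume)

    def to_dataframe(self):
        import pandas as pd

        ix, iy, iz = np.indices(self.grid.shape)
        return pd.DataFrame(
            {
                "ix": ix.ravel(),
                "iy": iy.ravel(),
                "iz": iz.ravel(),
                "value": self.grid.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_tiff(self, path) -> None:
        import tifffile

        # TIFF pages are z; grid is (x, y, z)
        tifffile.imwrite(str(path), self.grid.T.astype(np.float32))


def _grid_layout(network: LCNNetwork, subvolume_edge: float):
    if subvolume_edge <= 0:
        raise ValueError("subvolume_edge must be > 0")
    box = network.bounding_box
    origin = box[0]
    extent = np.maximum(box[1] - origin, 1e-9)
    shape = np.maximum(np.ceil(extent / subvolume_edge - 1e-12).astype(int), 1)
    return origin, tuple(shape)


def _clip_segment_to_cells(p0, p1, origin, edge, shape, accumulate):
    """Split segment p0→p1 at grid planes; call accumulate(cell, length)."""
    d = p1 - p0
    seg_len = math.sqrt(float(d @ d))
    if seg_len == 0.0:
        return
    # crossing parameters with grid planes along each axis
    ts = [0.0, 1.0]
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        lo = (p0[ax] - origin[ax]) / edge
        hi = (p1[ax] - origin[ax]) / edge
        k0, k1 = int(math.ceil(min(lo, hi))), int(math.floor(max(lo, hi)))
        for k in range(k0, k1 + 1):
            t = (origin[ax] + k * edge - p0[ax]) / d[ax]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts.sort()
    nx, ny, nz = shape
    for ta, tb in zip(ts[:-1], ts[1:]):
        if tb - ta <= 1e-15:
            continue
        tm = 0.5 * (ta + tb)
        mid = p0 + tm * d
        ix = min(max(int((mid[0] - origin[0]) / edge), 0), nx - 1)
        iy = min(max(int((mid[1] - origin[1]) / edge), 0), ny - 1)
        iz = min(max(int((mid[2] - origin[2]) / edge), 0), nz - 1)
        accumulate((ix, iy, iz), (tb - ta) * seg_len)


def canalicular_density_map(
    network: LCNNetwork, subvolume_edge: float = 8.0
) -> DensityMap:
    """Canalicular density Ca.Dn: canalicular length per unit volume.

    Each canaliculus (a straight segment between its endpoint positions)
    is clipped exactly at subvolume borders, so the map conserves total
    length: ``map.total() == sum of edge lengths`` (with edge lengths
    taken as the endpoint-to-endpoint distance).
    """
    origin, shape = _grid_layout(network, subvolume_edge)
    grid = np.zeros(shape)

    def accumulate(cell, length):
        grid[cell] += length

    rows = network.edge_rows()
    pos = network.positions
    for a, b in rows:
        _clip_segment_to_cells(
            pos[a], pos[b], origin, subvolume_edge, shape, accumulate
        )
    grid /= subvolume_edge**3
    return DensityMap(grid, subvolume_edge, origin.copy(), "canalicular_density")


def pore_density_map(network: LCNNetwork, subvolume_edge: float = 8.0) -> DensityMap:
    """Pore density: lacunar + vascular volume per unit volume.

    Each lacuna/vascular node's pore volume is given a spherical
    footprint of equivalent volume centred on the node and distributed
    over cells by deterministic fine-grid voxelization (exactly volume
    conserving).  Canalicular volume is excluded.
    """
    origin, shape = _grid_layout(network, subvolume_edge)
    grid = np.zeros(shape)
    mask = network.kind_mask(NodeKind.LACUNA, NodeKind.VASCULAR)
    nx, ny, nz = shape
    # body volume only: subtract the canalicular half-share from V_i
    half = network.canalicular_half_volumes()
    for row in np.flatnonzero(mask):
        vol = float(network.pore_volumes[row] - half[row])
        if vol <= 0:
            continue
        centre = network.positions[row]
        r = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
        # deterministic sub-sampling of the sphere: ~20 points per diameter
        n = 21
        h = 2.0 * r / n
        ax = centre[0] - r + (np.arange(n) + 0.5) * h
        ay = centre[1] - r + (np.arange(n) + 0.5) * h
        az = centre[2] - r + (np.arange(n) + 0.5) * h
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        inside = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (
            Z - centre[2]
        ) ** 2 <= r * r
        pts = np.column_stack([X[inside], Y[inside], Z[inside]])
        if len(pts) == 0:
            pts = centre.reshape(1, 3)
        w = vol / len(pts)  # normalize so the total is exactly `vol`
        idx = np.floor((pts - origin) / subvolume_edge).astype(int)
        idx[:, 0] = np.clip(idx[:, 0], 0, nx - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, ny - 1)
        idx[:, 2] = np.clip(idx[:, 2], 0, nz - 1)
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), w)
    grid /= subvolume_edge**3
    return DensityMap(grid, subvolume_edge, origin.copy(), "pore_density")
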