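"""Volumetric strain-rate fields driving the fluid-flow sources.

Two sources of strain rates are supported:

* a built-in Euler–Bernoulli beam-bending surrogate of axial tibial
  loading (linear strain profile across the cross-section about a
  neutral axis, with a configurable compressive/tensile asymmetry), and
* an imported voxel table of precomputed strain rates (e.g. from a
  finite-element model).

Compression is negative.  The cyclic loading waveform is triangular, so
the strain rate used as source amplitude is the constant ramp slope
``2 · frequency · peak_strain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import SurfaceGeometry
from .network import LCNNetwork


@dataclass
class LoadingProtocol:
    """Cyclic in vivo loading protocol (defaults: 1,200 µε peak at 4 Hz)."""

    peak_axial_strain: float = 1200e-6
    frequency: float = 4.0
    waveform: str = "triangular"
    poisson_ratio: float = 0.3

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValidationError("frequency must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValidationError("poisson_ratio must be in [0, 0.5)")


@dataclass
class StrainRateField:
    """Maps positions (n, 3) in µm to volumetric strain rates (1/s)."""

    evaluator: Callable[[np.ndarray], np.ndarray]
    provenance: str  # "beam_surrogate" | "imported"

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        out = np.asarray(self.evaluator(positions), dtype=float)
        return out.reshape(len(positions))


def triangular_strain_rate_amplitude(protocol: LoadingProtocol) -> float:
    """Ramp slope of the triangular load cycle, in 1/s.

    A 0 → peak → 0 triangle over one period has slope
    ``peak / (T/2) = 2 · f · peak``.
    """
    if protocol.waveform != "triangular":
        raise ValidationError(f"unsupported waveform {protocol.waveform!r}")
    return 2.0 * protocol.frequency * protocol.peak_axial_strain


def beam_bending_field(
    geometry: SurfaceGeometry,
    protocol: LoadingProtocol,
    neutral_axis_angle: float = 105.0,
    asymmetry: float = 1.4,
) -> StrainRateField:
    """Beam-bending surrogate strain-rate field over the cross-section.

    Axial strain is linear in the signed distance ``d`` from the neutral
    axis through the centroid; the tensile extreme of the periosteal
    boundary reaches ``peak_axial_strain`` exactly, and the compressive
    side is scaled by ``asymmetry`` (>1: compression exceeds tension, as
    in tibial bending).  Volumetric strain is ``axial · (1 − 2ν)``; the
    field value is the volumetric strain times the triangular ramp rate.

    ``neutral_axis_angle`` is given in the geometry's reporting
    convention (degrees).
    """
    raw = geometry.orientation * (neutral_axis_angle - geometry.angle_origin_deg)
    phi = np.radians(raw)
    # unit vector perpendicular to the neutral axis: the bending direction
    bend_dir = np.array([-np.sin(phi), np.cos(phi)])
    d_max = geometry.max_distance_along(bend_dir)
    if d_max <= 0:
        raise ValidationError("degenerate geometry: zero bending lever arm")
    amp = triangular_strain_rate_amplitude(protocol)
    nu = protocol.poisson_ratio
    centroid = geometry.centroid

    def evaluator(positions):
        d = (positions[:, :2] - centroid) @ bend_dir
        axial = protocol.peak_axial_strain * d / d_max
        axial = np.where(d < 0, asymmetry * axial, axial)
        volumetric = axial * (1.0 - 2.0 * nu)
        return volumetric * (amp / protocol.peak_axial_strain)

    return StrainRateField(evaluator, "beam_surrogate")


def import_strain_field(path) -> StrainRateField:
    """Nearest-neighbour strain-rate field from a CSV voxel table.

    Expects columns ``x_um, y_um, z_um, strain_rate_per_s``.  Positions
    outside the sampled cloud evaluate to the nearest sample.
    """
    import pandas as pd

    from .errors import SchemaError

    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise SchemaError(f"cannot parse strain table {path}: {exc}") from exc
    required = ["x_um", "y_um", "z_um", "strain_rate_per_s"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"strain table missing columns: {missing}", missing)
    if len(table) == 0:
        raise ValidationError("strain table is empty")
    bad = table[required].isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based line numbers
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"malformed strain table row at line {line}")
    points = table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    values = table["strain_rate_per_s"].to_numpy(dtype=float)
    tree = cKDTree(points)

    def evaluator(positions):
        _, idx = tree.query(positions, k=1)
        return values[idx]

    return StrainRateField(evaluator, "imported")


def sample_at_nodes(field: StrainRateField, network: LCNNetwork) -> np.ndarray:
    """Strain rate at every node, aligned with the network's node order."""
    if network.n_nodes == 0:
        return np.empty(0)
    return field(network.positions)
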