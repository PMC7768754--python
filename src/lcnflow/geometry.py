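"""Cross-section surface geometry and angular wedge discretization.

The cortical cross-section is bounded by two closed polylines: the
endocortical (inner) and periosteal (outer) surface.  Both surfaces are
discretized into ``wedge_count`` arc elements (180 by default, i.e. 2°
each) around the centroid; canaliculi and sample points are assigned to
wedges by the angle of their midpoint.

The angular convention of the *data* (e.g. "anterior at 15°, angles
increase counterclockwise") is metadata: ``angle_origin_deg`` and
``orientation`` map raw atan2 angles onto the reporting axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ValidationError


@dataclass
class SurfaceGeometry:
    """Annular cross-section geometry in the xy-plane (µm)."""

    centroid: np.ndarray
    endocortical_boundary: np.ndarray  # (k, 2) closed polyline vertices
    periosteal_boundary: np.ndarray
    wedge_count: int = 180
    angle_origin_deg: float = 0.0
    orientation: int = 1  # +1: angles increase counterclockwise

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(2)
        self.endocortical_boundary = np.asarray(
            self.endocortical_boundary, dtype=float
        ).reshape(-1, 2)
        self.periosteal_boundary = np.asarray(
            self.periosteal_boundary, dtype=float
        ).reshape(-1, 2)
        if self.wedge_count < 4:
            raise ValidationError("wedge_count must be >= 4")
        self._endo_ring = shapely.LinearRing(self.endocortical_boundary)
        self._perio_ring = shapely.LinearRing(self.periosteal_boundary)
        if not (self._endo_ring.is_valid and self._perio_ring.is_valid):
            raise ValidationError("boundary polyline is not a simple closed ring")
        endo_poly = shapely.Polygon(self._endo_ring)
        perio_poly = shapely.Polygon(self._perio_ring)
        if not perio_poly.contains(endo_poly):
            raise ValidationError(
                "endocortical boundary must lie inside the periosteal boundary"
            )
        self._cortex = shapely.Polygon(self._perio_ring, [self._endo_ring])

    # -- angles and wedges --------------------------------------------
    @property
    def wedge_width_deg(self) -> float:
        return 360.0 / self.wedge_count

    def angles_deg(self, xy: np.ndarray) -> np.ndarray:
        """Reporting-convention angle of points about the centroid, in [0, 360)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        raw = np.degrees(
            np.arctan2(xy[:, 1] - self.centroid[1], xy[:, 0] - self.centroid[0])
        )
        ang = self.orientation * raw + self.angle_origin_deg
        return np.mod(ang, 360.0)

    def wedge_of(self, xy: np.ndarray) -> np.ndarray:
        """Half-open wedge index: wedge w covers [w·width, (w+1)·width)."""
        idx = np.floor(self.angles_deg(xy) / self.wedge_width_deg).astype(int)
        return np.minimum(idx, self.wedge_count - 1)

    def wedge_centers_deg(self) -> np.ndarray:
        w = self.wedge_width_deg
        return (np.arange(self.wedge_count) + 0.5) * w

    # -- distances and membership -------------------------------------
    def distance_to_surface(self, xy: np.ndarray, surface: str) -> np.ndarray:
        """Euclidean distance from points to the requested boundary polyline."""
        ring = self._ring(surface)
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        pts = shapely.points(xy[:, 0], xy[:, 1])
        return shapely.distance(pts, ring)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """True for points inside the cortex (between the two boundaries)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return shapely.contains_xy(self._cortex, xy[:, 0], xy[:, 1])

    def cortex_sample_points(self, step: float) -> np.ndarray:
        """Regular grid of xy points inside the cortex, spacing ``step`` µm."""
        lo = self.periosteal_boundary.min(axis=0)
        hi = self.periosteal_boundary.max(axis=0)
        xs = np.arange(lo[0] + step / 2, hi[0], step)
        ys = np.arange(lo[1] + step / 2, hi[1], step)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        return pts[self.contains(pts)]

    def max_distance_along(self, direction: np.ndarray) -> float:
        """Largest positive projection of the periosteal boundary onto a direction."""
        d = np.asarray(direction, dtype=float).reshape(2)
        proj = (self.periosteal_boundary - self.centroid) @ d
        return float(proj.max())

    def _ring(self, surface: str):
        if surface == "endocortical":
            return self._endo_ring
        if surface == "periosteal":
            return self._perio_ring
        raise ValidationError(f"unknown surface {surface!r}")


def circular_geometry(
    inner_radius: float,
    outer_radius: float,
    centroid=(0.0, 0.0),
    n_vertices: int = 360,
    wedge_count: int = 180,
) -> SurfaceGeometry:
    """Concentric-circle cross-section (the synthetic default)."""
    if not 0 < inner_radius < outer_radius:
        raise ValidationError("need 0 < inner_radius < outer_radius")
    c = np.asarray(centroid, dtype=float)
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t)])
    return SurfaceGeometry(
        centroid=c,
        endocortical_boundary=c + inner_radius * ring,
        periosteal_boundary=c + outer_radius * ring,
        wedge_count=wedge_count,
    )


def geometry_to_dict(geom: SurfaceGeometry) -> dict:
    return {
        "centroid": geom.centroid.tolist(),
        "endocortical_boundary": geom.endocortical_boundary.tolist(),
        "periosteal_boundary": geom.periosteal_boundary.tolist(),
        "wedge_count": geom.wedge_count,
        "angle_origin_deg": geom.angle_origin_deg,
        "orientation": geom.orientation,
    }


def geometry_from_dict(d: dict) -> SurfaceGeometry:
    return SurfaceGeometry(
        centroid=np.asarray(d["centroid"]),
        endocortical_boundary=np.asarray(d["endocortical_boundary"]),
        periosteal_boundary=np.asarray(d["periosteal_boundary"]),
        wedge_count=int(d.get("wedge_count", 180)),
        angle_origin_deg=float(d.get("angle_origin_deg", 0.0)),
        orientation=int(d.get("orientation", 1)),
    )
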