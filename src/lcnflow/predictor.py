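"""Surface mechanoresponse predictors and their scoring.

For each 2° wedge of the cross-section, the flow predictor is the
exponentially distance-weighted mean of canalicular fluid velocities,

    P_w = ( Σ_j w_j l_j )⁻¹ Σ_j |v_j| l_j w_j,    w_j = exp(−r_j / R),

summed over the canaliculi whose midpoint falls in wedge w, with r_j
the distance from the canaliculus midpoint to the surface of interest
and R the decay length (default 15 µm).  Contributions close to the
surface dominate (Mullender–Huiskes weighting); the normalization makes
the predictor a true weighted mean, so a wedge of constant velocity
returns that constant.

The strain predictor applies the same weighting to |volumetric strain
rate| sampled on a regular grid of points in the cortex.  Profiles are
smoothed with a circular 30° triangular moving average, mapped to
measured (re)modeling thickness by a jointly fitted affine calibration,
and scored with the root-mean-square error over the N wedges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .flow import FlowSolution
from .geometry import SurfaceGeometry
from .network import LCNNetwork
from .strain import StrainRateField

logger = logging.getLogger(__name__)

SURFACES = ("endocortical", "periosteal")


@dataclass
class PredictorConfig:
    """Tunables of the surface predictor."""

    decay_length: float = 15.0  # R, µm
    smoothing_window: float = 30.0  # degrees
    sampling_step: float = 2.0  # µm, strain-predictor grid spacing

    def __post_init__(self):
        if self.decay_length <= 0:
            raise ValidationError("decay_length must be > 0")


@dataclass
class SurfaceProfile:
    """Per-wedge values on the circular angular axis (index 0 adjacent to -1)."""

    values: np.ndarray
    surface: str  # "endocortical" | "periosteal"
    quantity: str  # "flow_predictor" | "strain_predictor" | "remodeling_thickness"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    @property
    def wedge_count(self) -> int:
        return len(self.values)

    def to_dataframe(self, geometry: SurfaceGeometry | None = None):
        import pandas as pd

        n = self.wedge_count
        width = 360.0 / n
        return pd.DataFrame(
            {
                "wedge_index": np.arange(n),
                "angle_deg": (np.arange(n) + 0.5) * width,
                "value": self.values,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_profile(path, surface: str, quantity: str = "remodeling_thickness"):
    """Read a per-wedge profile CSV (wedge_index, angle_deg, value)."""
    import pandas as pd

    from .errors import SchemaError

    table = pd.read_csv(path)
    missing = [c for c in ("wedge_index", "value") if c not in table.columns]
    if missing:
        raise SchemaError(f"profile CSV missing columns: {missing}", missing)
    table = table.sort_values("wedge_index")
    return SurfaceProfile(table["value"].to_numpy(), surface, quantity)


@dataclass
class WedgeAssignment:
    """Per-canaliculus wedge index, lengths and distances to both surfaces."""

    wedge: np.ndarray  # (m,) int
    lengths: np.ndarray  # (m,) µm
    r_endocortical: np.ndarray  # (m,) µm
    r_periosteal: np.ndarray  # (m,) µm
    wedge_count: int

    def r_to(self, surface: str) -> np.ndarray:
        if surface == "endocortical":
            return self.r_endocortical
        if surface == "periosteal":
            return self.r_periosteal
        raise ValidationError(f"unknown surface {surface!r}")


def assign_wedges(network: LCNNetwork, geometry: SurfaceGeometry) -> WedgeAssignment:
    """Assign every canaliculus to the wedge containing its midpoint."""
    mid = network.edge_midpoints()[:, :2]
    return WedgeAssignment(
        wedge=geometry.wedge_of(mid),
        lengths=network.lengths.copy(),
        r_endocortical=geometry.distance_to_surface(mid, "endocortical"),
        r_periosteal=geometry.distance_to_surface(mid, "periosteal"),
        wedge_count=geometry.wedge_count,
    )


def _weighted_wedge_mean(values, lengths, r, wedge, wedge_count, decay_length):
    w = np.exp(-r / decay_length)
    wl = w * lengths
    num = np.bincount(wedge, weights=values * wl, minlength=wedge_count)
    den = np.bincount(wedge, weights=wl, minlength=wedge_count)
    empty = den == 0
    if empty.any():
        logger.debug("%d empty wedges set to 0", int(empty.sum()))
    return np.divide(num, den, out=np.zeros(wedge_count), where=~empty)


def flow_predictor(
    solution: FlowSolution,
    assignment: WedgeAssignment,
    config: PredictorConfig,
    surface: str,
) -> SurfaceProfile:
    """Distance-weighted mean |v| per wedge (the flow mechanoresponse predictor)."""
    values = _weighted_wedge_mean(
        np.abs(solution.edge_velocity),
        assignment.lengths,
        assignment.r_to(surface),
        assignment.wedge,
        assignment.wedge_count,
        config.decay_length,
    )
    return SurfaceProfile(values, surface, "flow_predictor")


def strain_predictor(
    field: StrainRateField,
    geometry: SurfaceGeometry,
    config: PredictorConfig,
    surface: str,
    z: float = 0.0,
) -> SurfaceProfile:
    """Distance-weighted mean |strain rate| per wedge, sampled on a grid."""
    pts2 = geometry.cortex_sample_points(config.sampling_step)
    if len(pts2) == 0:
        raise ValidationError("no sample points inside the cortex")
    pts3 = np.column_stack([pts2, np.full(len(pts2), z)])
    values = np.abs(field(pts3))
    wedge = geometry.wedge_of(pts2)
    r = geometry.distance_to_surface(pts2, surface)
    profile = _weighted_wedge_mean(
        values,
        np.ones(len(pts2)),
        r,
        wedge,
        geometry.wedge_count,
        config.decay_length,
    )
    return SurfaceProfile(profile, surface, "strain_predictor")


def triangular_smooth(profile: SurfaceProfile, window: float = 30.0) -> SurfaceProfile:
    """Circular triangular moving average of total width ``window`` degrees.

    The kernel peaks at the central wedge, falls linearly to zero at
    ±window/2 and is normalized to sum 1, so the circular mean of the
    profile is preserved exactly.
    """
    n = profile.wedge_count
    width = 360.0 / n
    bins = window / width
    if abs(bins - round(bins)) > 1e-9:
        raise ValidationError("window must be a multiple of the wedge width")
    half_bins = bins / 2.0
    m = int(np.ceil(half_bins))
    if m <= 1:
        return replace(profile, values=profile.values.copy())
    offsets = np.arange(-m + 1, m)
    kernel = 1.0 - np.abs(offsets) / half_bins
    kernel /= kernel.sum()
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    smoothed = (profile.values[idx] * kernel[None, :]).sum(axis=1)
    return replace(profile, values=smoothed)


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    calibrated: list


def calibrate(
    predicted: SurfaceProfile | Sequence[SurfaceProfile],
    measured: SurfaceProfile | Sequence[SurfaceProfile],
) -> CalibrationResult:
    """Affine map from predictor units to µm, fitted jointly by least squares.

    The same (slope, intercept) is used for all supplied profiles (e.g.
    both surfaces of one animal); a negative fitted slope is clipped to
    0 (the predictor is a magnitude and cannot anticorrelate by design).
    """
    preds = [predicted] if isinstance(predicted, SurfaceProfile) else list(predicted)
    meas = [measured] if isinstance(measured, SurfaceProfile) else list(measured)
    if len(preds) != len(meas):
        raise ValidationError("predicted/measured profile counts differ")
    for p, m in zip(preds, meas):
        if p.wedge_count != m.wedge_count:
            raise ValidationError("profile wedge counts differ")
    x = np.concatenate([p.values for p in preds])
    y = np.concatenate([m.values for m in meas])
    if np.ptp(x) == 0:
        logger.warning("constant predictor: calibration degenerates to the mean")
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
        if slope < 0:
            slope, intercept = 0.0, float(y.mean())
    calibrated = [
        replace(p, values=slope * p.values + intercept, quantity="remodeling_thickness")
        for p in preds
    ]
    return CalibrationResult(float(slope), float(intercept), calibrated)


def rmse(predicted: SurfaceProfile, measured: SurfaceProfile) -> float:
    """Root-mean-square error between two per-wedge profiles (µm)."""
    if predicted.wedge_count != measured.wedge_count:
        raise ValidationError("profile lengths differ")
    d = predicted.values - measured.values
    return float(np.sqrt(np.mean(d * d)))


def score_calibrated(
    predicted: Sequence[SurfaceProfile], measured: Sequence[SurfaceProfile]
) -> dict:
    """Calibrate jointly, then RMSE per surface; returns a summary dict."""
    cal = calibrate(list(predicted), list(measured))
    out = {
        "slope": cal.slope,
        "intercept": cal.intercept,
        "rmse": {},
    }
    for p, m in zip(cal.calibrated, measured):
        out["rmse"][p.surface] = rmse(p, m)
    return out


def r_sensitivity(
    solution: FlowSolution,
    assignment: WedgeAssignment,
    measured: dict,
    R_values: Iterable[float],
    config: PredictorConfig | None = None,
):
    """RMSE of the calibrated flow predictor as a function of the decay length R.

    ``measured`` maps surface name to its measured-thickness profile.
    Returns a DataFrame with columns ``R_um`` and ``rmse_um`` (mean over
    the supplied surfaces).
    """
    import pandas as pd

    config = config or PredictorConfig()
    rows = []
    surfaces = sorted(measured)
    for R in R_values:
        cfg = replace(config, decay_length=float(R))
        preds = [
            triangular_smooth(
                flow_predictor(solution, assignment, cfg, s), cfg.smoothing_window
            )
            for s in surfaces
        ]
        meas = [measured[s] for s in surfaces]
        summary = score_calibrated(preds, meas)
        rows.append(
            {"R_um": float(R), "rmse_um": float(np.mean(list(summary["rmse"].values())))}
        )
    return pd.DataFrame(rows)
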