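"""End-to-end pipeline configuration and execution.

A :class:`PipelineConfig` mirrors the per-stage parameters (threshold,
voxel size, hydraulic constants, predictor decay length, ...).  A run
executes segment → network → strain → solve → predict → score for the
configured entry point (TIFF image, network file, or synthetic spec)
and writes all products plus a manifest recording the configuration
hash and seeds, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ValidationError
from .flow import (
    FlowProblem,
    HydraulicParameters,
    assemble_conductances,
    compute_sources,
    default_boundary_nodes,
    solve_flow,
)
from .geometry import geometry_from_dict, geometry_to_dict
from .network import read_network, write_network
from .predictor import (
    PredictorConfig,
    assign_wedges,
    flow_predictor,
    read_profile,
    score_calibrated,
    strain_predictor,
    triangular_smooth,
)
from .strain import LoadingProtocol, beam_bending_field, import_strain_field, sample_at_nodes
from .synthetic import (
    SyntheticSpec,
    generate_response,
    run_flow_pipeline,
    synthetic_experiment,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their package-wide defaults."""

    # image stage
    threshold: float = 100.0
    voxel_size: float = 0.37
    lacuna_min_volume: float = 50.0
    vascular_min_volume: float = 1000.0
    lacuna_opening_radius: float = 1.0
    # hydraulics
    cross_section_area: float = 0.045
    effective_permeability: float = 1e-7
    fluid_viscosity: float = 1e-3
    # loading
    peak_axial_strain: float = 1200e-6
    frequency: float = 4.0
    poisson_ratio: float = 0.3
    neutral_axis_angle: float = 105.0
    asymmetry: float = 1.4
    # predictor
    decay_length: float = 15.0
    smoothing_window: float = 30.0
    wedge_count: int = 180
    sampling_step: float = 2.0
    # synthetic
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config YAML must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def hydraulic_parameters(self) -> HydraulicParameters:
        return HydraulicParameters(
            cross_section_area=self.cross_section_area,
            effective_permeability=self.effective_permeability,
            fluid_viscosity=self.fluid_viscosity,
        )

    def loading_protocol(self) -> LoadingProtocol:
        return LoadingProtocol(
            peak_axial_strain=self.peak_axial_strain,
            frequency=self.frequency,
            poisson_ratio=self.poisson_ratio,
        )

    def predictor_config(self) -> PredictorConfig:
        return PredictorConfig(
            decay_length=self.decay_length,
            smoothing_window=self.smoothing_window,
            sampling_step=self.sampling_step,
        )


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    synthetic_spec: SyntheticSpec | None = None,
    network_path=None,
    geometry_path=None,
    strain_path=None,
    measured_paths: dict | None = None,
) -> dict:
    """Run the configured pipeline end to end and write a result bundle.

    Entry points (exactly one): a synthetic spec, or a network file
    (GraphML) plus geometry JSON (with optional imported strain table
    and measured-response CSVs).  Returns the summary dict that is also
    written as ``summary.json``; the manifest records the config hash
    and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.hydraulic_parameters()
    protocol = config.loading_protocol()
    cfg = config.predictor_config()

    if synthetic_spec is not None:
        exp = synthetic_experiment(
            synthetic_spec,
            true_R=config.decay_length,
            params=params,
            protocol=protocol,
            neutral_axis_angle=config.neutral_axis_angle,
            asymmetry=config.asymmetry,
        )
        network, geometry = exp.network, exp.geometry
        solution, assignment = exp.solution, exp.assignment
        field = exp.strain_field
        measured = exp.measured
        write_network(network, out / "network.graphml", "graphml")
        write_network(network, out / "network", "csv_edge_list")
        with open(out / "geometry.json", "w") as fh:
            json.dump(geometry_to_dict(geometry), fh)
        for s, prof in measured.items():
            prof.write_csv(out / f"measured_{s}.csv")
    elif network_path is not None:
        if geometry_path is None:
            raise ValidationError("a geometry JSON is required with a network input")
        network = read_network(network_path, "graphml")
        with open(geometry_path) as fh:
            geometry = geometry_from_dict(json.load(fh))
        assemble_conductances(network, params)
        if strain_path is not None:
            field = import_strain_field(strain_path)
        else:
            field = beam_bending_field(
                geometry, protocol, config.neutral_axis_angle, config.asymmetry
            )
        rates = sample_at_nodes(field, network)
        sources = compute_sources(network, rates, params)
        problem = FlowProblem(network, sources, default_boundary_nodes(network))
        solution = solve_flow(problem)
        assignment = assign_wedges(network, geometry)
        measured = {}
        for surf, path in (measured_paths or {}).items():
            measured[surf] = read_profile(path, surf)
    else:
        raise ValidationError("provide either a synthetic spec or a network input")

    solution.write_csv(network, out / "flow_edges.csv", out / "flow_nodes.csv")

    surfaces = ("endocortical", "periosteal")
    flow_profiles = {
        s: triangular_smooth(
            flow_predictor(solution, assignment, cfg, s), cfg.smoothing_window
        )
        for s in surfaces
    }
    strain_profiles = {
        s: triangular_smooth(
            strain_predictor(field, geometry, cfg, s), cfg.smoothing_window
        )
        for s in surfaces
    }
    for s in surfaces:
        flow_profiles[s].write_csv(out / f"flow_predictor_{s}.csv")
        strain_profiles[s].write_csv(out / f"strain_predictor_{s}.csv")

    summary: dict = {"n_nodes": network.n_nodes, "n_edges": network.n_edges}
    if measured:
        surfs = sorted(measured)
        summary["flow"] = score_calibrated(
            [flow_profiles[s] for s in surfs], [measured[s] for s in surfs]
        )
        summary["strain"] = score_calibrated(
            [strain_profiles[s] for s in surfs], [measured[s] for s in surfs]
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {
        "lcnflow_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": None if synthetic_spec is None else synthetic_spec.seed,
        "entry_point": "synthetic" if synthetic_spec is not None else "network",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
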