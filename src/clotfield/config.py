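"""Run configuration: a schema-validated description of one pipeline run.

A run config has geometry, flow, tracking, kinetics, solver and metrics
sections; unknown keys are rejected before any computation.  Two frozen
profiles serve as the package's reference cases: a straight-channel control
with monotone throughflow and an aneurysm with a recirculating bulge.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from . import mesh as meshmod
from .flow import FlowCase, make_pulsatile_poiseuille, make_recirculating_field
from .kinetics import GranuleContents, KineticParameters
from .metrics import CriticalThresholds
from .solver import BoundarySpec, RADConfig, DIFFUSIVITY_DEFAULTS, TABLE_DEFAULTS


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Section):
    kind: Literal["channel", "aneurysm"]
    length: float = 2.0
    half_height: float = 0.15
    proximal_radius: float = 0.15
    bulge_radius: float = 0.4
    proximal_length: float = 1.0
    bulge_length: float = 1.5
    distal_length: float = 1.0
    resolution: float = 0.03


class FlowSection(_Section):
    kind: Literal["poiseuille", "recirculating"]
    period: float = 0.8
    n_frames: int = 20
    mean_peak_velocity: float = 10.0
    pulsatility_amplitude: float = 0.5
    throughflow_velocity: float = 10.0
    vortex_strength: float = 0.5
    vortex_pulsatility: float = 0.8
    vortex_phase_lag: float = 1.5707963267948966  # pi/2
    viscosity: float = 0.04


class TrackingSection(_Section):
    dt: float | None = None            # default period / 1000
    max_cycles: int = 30
    n_release_times: int = 4
    stagnation_tol: float | None = None


class KineticsSection(_Section):
    k_AP_AP: float = 0.3
    k_AP_SR: float = 0.6
    k_AP_IIa: float = 0.0
    srcum_lo: float = 250.0
    srcum_hi: float = 500.0
    adp_lo: float = 200.0
    adp_hi: float = 1000.0
    adp_content: float = 3.0
    polyp_content: float = 0.74
    release_fraction: float = 0.75
    platelet_count: float = 2.5e11
    reference_concentration: float = 10.0


class SolverSection(_Section):
    dt: float | None = None            # default period / 200
    n_cycles: int = 10
    diffusivity_RP: float = DIFFUSIVITY_DEFAULTS["RP"]
    diffusivity_AP: float = DIFFUSIVITY_DEFAULTS["AP"]
    diffusivity_ADP: float = DIFFUSIVITY_DEFAULTS["ADP"]
    diffusivity_PolyP: float = DIFFUSIVITY_DEFAULTS["PolyP"]
    supg: bool = True
    clip_negative: bool = True
    theta: float = 1.0
    snapshots_per_cycle: int = 1
    inlet_RP: float = TABLE_DEFAULTS["RP"]
    inlet_AP: float = TABLE_DEFAULTS["AP"]
    inlet_ADP: float = TABLE_DEFAULTS["ADP"]
    inlet_PolyP: float = TABLE_DEFAULTS["PolyP"]


class MetricsSection(_Section):
    adp_crit: float = 1000.0
    polyp_crit_mass: float = 2.0
    polyp_monomer_mw: float = 101.98
    polyp_chain_length: float = 75.0
    region_factor: float = 1.1
    tawss_threshold: float = 1.0


class RunConfig(_Section):
    label: str = "case"
    geometry: GeometrySection
    flow: FlowSection
    tracking: TrackingSection = TrackingSection()
    kinetics: KineticsSection = KineticsSection()
    solver: SolverSection = SolverSection()
    metrics: MetricsSection = MetricsSection()
    log_level: str = "INFO"

    def digest(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML (or JSON) run configuration."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(data)


# -- object builders --------------------------------------------------------

def build_mesh(cfg: RunConfig) -> meshmod.Mesh:
    g = cfg.geometry
    if g.kind == "channel":
        return meshmod.build_channel_mesh(g.length, g.half_height, g.resolution)
    return meshmod.build_aneurysm_mesh(
        g.proximal_radius, g.bulge_radius, g.proximal_length,
        g.bulge_length, g.distal_length, g.resolution,
    )


def build_case(cfg: RunConfig, mesh: meshmod.Mesh | None = None) -> FlowCase:
    mesh = mesh if mesh is not None else build_mesh(cfg)
    f = cfg.flow
    if f.kind == "poiseuille":
        field = make_pulsatile_poiseuille(
            mesh, f.mean_peak_velocity, f.pulsatility_amplitude, f.period, f.n_frames
        )
    else:
        field = make_recirculating_field(
            mesh, f.throughflow_velocity, f.vortex_strength, f.period, f.n_frames,
            pulsatility_amplitude=f.pulsatility_amplitude,
            vortex_pulsatility=f.vortex_pulsatility,
            vortex_phase_lag=f.vortex_phase_lag,
        )
    return FlowCase(mesh, field, f.period, viscosity=f.viscosity, label=cfg.label)


def kinetic_parameters(cfg: RunConfig) -> KineticParameters:
    k = cfg.kinetics
    contents = GranuleContents(
        adp_content=k.adp_content, polyp_content=k.polyp_content,
        release_fraction=k.release_fraction, platelet_count=k.platelet_count,
        reference_concentration=k.reference_concentration,
    )
    from .kinetics import released_coefficient

    return KineticParameters(
        k_AP_AP=k.k_AP_AP, k_AP_SR=k.k_AP_SR, k_AP_IIa=k.k_AP_IIa,
        ADP_rel=released_coefficient(contents, "ADP"),
        PolyP_rel=released_coefficient(contents, "PolyP"),
        srcum_lo=k.srcum_lo, srcum_hi=k.srcum_hi,
        adp_lo=k.adp_lo, adp_hi=k.adp_hi,
    )


def rad_config(cfg: RunConfig) -> RADConfig:
    s = cfg.solver
    return RADConfig(
        dt=s.dt, n_cycles=s.n_cycles,
        diffusivities={
            "RP": s.diffusivity_RP, "AP": s.diffusivity_AP,
            "ADP": s.diffusivity_ADP, "PolyP": s.diffusivity_PolyP,
        },
        supg=s.supg, clip_negative=s.clip_negative, theta=s.theta,
        snapshots_per_cycle=s.snapshots_per_cycle,
    )


def boundary_spec(cfg: RunConfig) -> BoundarySpec:
    s = cfg.solver
    return BoundarySpec(inlet_values={
        "RP": s.inlet_RP, "AP": s.inlet_AP, "ADP": s.inlet_ADP, "PolyP": s.inlet_PolyP,
    })


def critical_thresholds(cfg: RunConfig) -> CriticalThresholds:
    m = cfg.metrics
    return CriticalThresholds(
        adp_crit=m.adp_crit, polyp_crit_mass=m.polyp_crit_mass,
        polyp_monomer_mw=m.polyp_monomer_mw, polyp_chain_length=m.polyp_chain_length,
    )


# -- frozen reference profiles ----------------------------------------------

def default_control_config() -> RunConfig:
    """Straight-channel control: pulsatile Poiseuille flow, full washout."""
    return RunConfig(
        label="control",
        geometry=GeometrySection(kind="channel", length=2.0, half_height=0.15,
                                 resolution=0.05),
        flow=FlowSection(kind="poiseuille", period=0.8, n_frames=20,
                         mean_peak_velocity=20.0, pulsatility_amplitude=0.5),
    )


def default_aneurysm_config() -> RunConfig:
    """Idealized aneurysm: throughflow + bulge vortex with a stagnation zone."""
    return RunConfig(
        label="aneurysm",
        geometry=GeometrySection(kind="aneurysm", proximal_radius=0.15,
                                 bulge_radius=0.4, proximal_length=1.0,
                                 bulge_length=1.5, distal_length=1.0,
                                 resolution=0.05),
        flow=FlowSection(kind="recirculating", period=0.8, n_frames=20,
                         throughflow_velocity=4.0, vortex_strength=3.0,
                         vortex_pulsatility=0.6, pulsatility_amplitude=0.2),
    )
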