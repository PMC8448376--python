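"""Pro-coagulant environment quantification.

Volume fractions of a region where activated-platelet concentration meets
activation levels (AP_x, full activation at [AP] >= 10 nM), agonist
critical-threshold fractions ([ADP] >= 1 uM; [PolyP] >= 2 ug/ml converted to
the model's molar units), per-element dominance of the mechanical vs the
biochemical activation channel, and wall shear exposure (TAWSS and the
low-WSS area fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import FlowCase
from .kinetics import KineticParameters, SpeciesState, activation_rates
from .lagrangian import CumulativeShearField
from .mesh import WALL, Mesh

DOMINANCE_RATE_FLOOR = 1e-12  # nM/s; below it an element counts as inactive


def polyp_mass_to_molar(mass_ug_per_ml: float, monomer_mw: float) -> float:
    """Convert a PolyP mass concentration (ug/ml) to nM of the given unit MW.

    ug/ml = mg/l; mg/l divided by g/mol gives mmol/m^3 = uM, hence x1000 nM.
    """
    if monomer_mw == 0:
        raise ValueError("molecular weight must be non-zero")
    if mass_ug_per_ml < 0 or monomer_mw < 0:
        raise ValueError("mass and molecular weight must be non-negative")
    return mass_ug_per_ml * 1e6 / monomer_mw


@dataclass
class CriticalThresholds:
    """Agonist critical concentrations.

    The PolyP threshold is reported in the literature as a mass concentration
    (2 ug/ml).  The transported PolyP field inherits the model units of the
    release stoichiometry, which for platelet polyP (chains of ~60-100
    phosphate residues) is per-chain: the default conversion therefore uses
    chain MW = polyp_chain_length * monomer MW.  Setting polyp_chain_length=1
    gives the strict per-monomer reading (2 ug/ml = 19611.7 nM monomer), a
    level the release stoichiometry can never reach.
    """

    adp_crit: float = 1000.0           # nM
    polyp_crit_mass: float = 2.0       # ug/ml
    polyp_monomer_mw: float = 101.98   # g/mol, NaPO3 residue
    polyp_chain_length: float = 75.0   # residues per chain

    def __post_init__(self):
        if min(self.adp_crit, self.polyp_crit_mass, self.polyp_monomer_mw,
               self.polyp_chain_length) <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def polyp_crit_nM(self) -> float:
        return polyp_mass_to_molar(
            self.polyp_crit_mass, self.polyp_monomer_mw * self.polyp_chain_length
        )


@dataclass
class ProCoagulantReport:
    ap_fractions: dict[str, float]
    adp_critical_fraction: float
    polyp_critical_fraction: float
    dominance_series: list[dict[str, float]]
    snapshot_times: list[float]
    tawss_low_area_fraction: float | None = None
    thresholds: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProCoagulantReport":
        return cls(**json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        rows = [{"time": t, **d} for t, d in zip(self.snapshot_times, self.dominance_series)]
        pd.DataFrame(rows).to_csv(path, index=False)


def _element_means(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    return nodal[mesh.elements].mean(axis=1)


def volume_fraction_above(
    field: np.ndarray,
    mesh: Mesh,
    threshold: float,
    region_mask: np.ndarray | None = None,
) -> float:
    """Measure fraction of the region whose element-mean field >= threshold.

    ``field`` may be nodal (averaged per element) or already per-element.
    """
    if region_mask is None:
        region_mask = np.ones(len(mesh.elements), dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region")
    vals = np.asarray(field, dtype=float)
    if vals.shape == (len(mesh.nodes),):
        vals = _element_means(mesh, vals)
    if vals.shape != (len(mesh.elements),):
        raise ValueError("field must be nodal or per-element")
    w = mesh.element_measures[region_mask]
    above = vals[region_mask] >= threshold
    return float(np.sum(w[above]) / np.sum(w))


def ap_fractions(
    state: SpeciesState,
    mesh: Mesh | None = None,
    full_activation: float = 10.0,
    levels: tuple[float, ...] = (5.0, 8.0, 10.0),
    region_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """AP_x volume fractions: fraction of the region with [AP] >= level (nM).

    Keys are percentages of full activation ("AP_50", "AP_80", "AP_100").
    """
    mesh = mesh or state.mesh
    out = {}
    for level in levels:
        pct = int(round(100.0 * level / full_activation))
        out[f"AP_{pct}"] = volume_fraction_above(state.ap, mesh, level, region_mask)
    vals = list(out.values())
    if any(a < b - 1e-14 for a, b in zip(vals, vals[1:])):
        raise AssertionError("AP_x nesting violated: fractions must be non-increasing")
    return out


def agonist_critical_fractions(
    state: SpeciesState,
    mesh: Mesh | None = None,
    thresholds: CriticalThresholds | None = None,
    region_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """(ADP, PolyP) volume fractions above their critical thresholds."""
    mesh = mesh or state.mesh
    thresholds = thresholds or CriticalThresholds()
    f_adp = volume_fraction_above(state.adp, mesh, thresholds.adp_crit, region_mask)
    f_polyp = volume_fraction_above(state.polyp, mesh, thresholds.polyp_crit_nM, region_mask)
    return f_adp, f_polyp


def activation_dominance(
    state: SpeciesState,
    srcum_field: CumulativeShearField | np.ndarray,
    params: KineticParameters | None = None,
    mesh: Mesh | None = None,
    region_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Label each element mechanical / biochemical / inactive.

    Compares the element-mean mechanical activation rate A(SRcum)*[RP]
    against the biochemical rate k_AP_AP*f([ADP])*[AP]*[RP]; elements where
    both are below the rate floor are inactive.  Returns (labels, measure
    fractions over the region); fractions sum to 1.
    """
    params = params or KineticParameters()
    mesh = mesh or state.mesh
    if isinstance(srcum_field, CumulativeShearField):
        src = np.nan_to_num(srcum_field.element_mean)
    else:
        src = np.asarray(srcum_field, dtype=float)
        if src.shape == (len(mesh.nodes),):
            src = _element_means(mesh, src)
    if src.shape != (len(mesh.elements),):
        raise ValueError("cumulative shear field does not match the mesh")
    rp = _element_means(mesh, state.rp)
    ap = _element_means(mesh, state.ap)
    adp = _element_means(mesh, state.adp)
    bio, mech, _ = activation_rates(rp, ap, adp, src, params)
    labels = np.where(
        (bio < DOMINANCE_RATE_FLOOR) & (mech < DOMINANCE_RATE_FLOOR),
        "inactive",
        np.where(mech > bio, "mechanical", "biochemical"),
    )
    if region_mask is None:
        region_mask = np.ones(len(mesh.elements), dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region")
    w = mesh.element_measures[region_mask]
    total = np.sum(w)
    fractions = {
        lab: float(np.sum(w[labels[region_mask] == lab]) / total)
        for lab in ("mechanical", "biochemical", "inactive")
    }
    return labels, fractions


def tawss_field(case: FlowCase) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged wall shear stress per wall facet (dyne/cm^2).

    Returns (tawss, facet_lengths).  WSS per facet is the magnitude of the
    tangential component of the viscous traction mu*(grad u + grad u^T)*n of
    the adjacent element, averaged over the stored frames (one period).
    """
    mesh = case.mesh
    wall_sel = mesh.facet_tags == WALL
    facets = mesh.boundary_facets[wall_sel]
    if len(facets) == 0:
        raise ValueError("mesh has no wall facets")
    # adjacent element per facet: the unique element containing both nodes
    elem_of = {}
    for e, tri in enumerate(mesh.elements):
        s = set(tri)
        for pair in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            elem_of[frozenset(pair)] = e
    adj = np.array([elem_of[frozenset(f)] for f in map(tuple, facets)])

    a = mesh.nodes[facets[:, 0]]
    b = mesh.nodes[facets[:, 1]]
    tangent = b - a
    lengths = np.linalg.norm(tangent, axis=1)
    tangent = tangent / lengths[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    tawss = np.zeros(len(facets))
    frames = case.field.frame_times
    for t in frames:
        G = case.field.element_gradients(float(t))[adj]       # (F, 2, 2)
        sig = case.viscosity * (G + np.swapaxes(G, 1, 2))
        traction = np.einsum("fab,fb->fa", sig, normal)
        tawss += np.abs(np.einsum("fa,fa->f", traction, tangent)) / len(frames)
    return tawss, lengths


def area_fraction_low_wss(
    tawss: np.ndarray, lengths: np.ndarray, threshold: float = 1.0
) -> float:
    """Wall area (facet length in 2D) fraction with TAWSS below threshold."""
    return float(np.sum(lengths[tawss < threshold]) / np.sum(lengths))


def report(
    states: list[SpeciesState],
    srcum_field: CumulativeShearField | np.ndarray,
    params: KineticParameters | None = None,
    thresholds: CriticalThresholds | None = None,
    region_mask: np.ndarray | None = None,
    case: FlowCase | None = None,
) -> ProCoagulantReport:
    """Assemble the full pro-coagulant report from a snapshot series."""
    if not states:
        raise ValueError("empty snapshot series")
    params = params or KineticParameters()
    thresholds = thresholds or CriticalThresholds()
    final = states[-1]
    mesh = final.mesh
    apf = ap_fractions(final, mesh, region_mask=region_mask)
    f_adp, f_polyp = agonist_critical_fractions(final, mesh, thresholds, region_mask)
    series = []
    for st in states:
        _, fr = activation_dominance(st, srcum_field, params, mesh, region_mask)
        series.append(fr)
    tawss_frac = None
    if case is not None:
        tawss, lengths = tawss_field(case)
        tawss_frac = area_fraction_low_wss(tawss, lengths)
    return ProCoagulantReport(
        ap_fractions=apf,
        adp_critical_fraction=f_adp,
        polyp_critical_fraction=f_polyp,
        dominance_series=series,
        snapshot_times=[float(s.time) for s in states],
        tawss_low_area_fraction=tawss_frac,
        thresholds={
            "adp_crit_nM": thresholds.adp_crit,
            "polyp_crit_mass_ug_per_ml": thresholds.polyp_crit_mass,
            "polyp_monomer_mw": thresholds.polyp_monomer_mw,
            "polyp_chain_length": thresholds.polyp_chain_length,
            "polyp_crit_nM": thresholds.polyp_crit_nM,
        },
    )
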