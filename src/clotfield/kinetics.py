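"""Platelet activation kinetics and agonist release.

Four species are tracked: resting platelets [RP], activated platelets [AP]
(both in model nM, 10 nM total circulating platelets with 5% activated),
ADP (nM) and platelet polyphosphate PolyP (nM).  Platelets activate through
two channels:

* mechanically, at rate k_AP_SR * f(SRcum) with f a ramp in the cumulative
  shear rate between srcum_lo and srcum_hi;
* biochemically, at rate k_AP_AP * f([ADP]) * [AP] * [RP], the ADP-gated
  autocatalytic contact reaction, with f a ramp between the reversible
  (0.2 uM) and irreversible (1 uM) ADP activation thresholds.

Thrombin-mediated activation (k_AP_IIa) exists in the interface but defaults
to zero: the model targets thrombus initiation before thrombin generation.
Each unit of newly activated platelet releases dense-granule agonists in
fixed proportion: ADP_rel and PolyP_rel concentration units per unit of AP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .mesh import Mesh


@dataclass
class KineticParameters:
    """Reaction rates (literature values) and activation-ramp thresholds.

    k_AP_AP is 3e8 M^-1 s^-1 converted once to nM^-1 s^-1.
    """

    k_AP_AP: float = 0.3        # nM^-1 s^-1
    k_AP_SR: float = 0.6        # s^-1
    k_AP_IIa: float = 0.0       # s^-1 (thrombin channel, off)
    ADP_rel: float = 562.5      # dimensionless release ratio
    PolyP_rel: float = 138.75   # dimensionless release ratio
    srcum_lo: float = 250.0
    srcum_hi: float = 500.0
    adp_lo: float = 200.0       # nM
    adp_hi: float = 1000.0      # nM

    def __post_init__(self):
        for name in ("k_AP_AP", "k_AP_SR", "k_AP_IIa", "ADP_rel", "PolyP_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.srcum_lo < self.srcum_hi:
            raise ValueError("srcum_lo must be below srcum_hi")
        if not self.adp_lo < self.adp_hi:
            raise ValueError("adp_lo must be below adp_hi")


@dataclass
class GranuleContents:
    """Dense-granule inventory used to derive the release ratios."""

    adp_content: float = 3.0          # mol per 1e17 platelets
    polyp_content: float = 0.74       # mol per 1e17 platelets (0.743 in some sources)
    release_fraction: float = 0.75
    platelet_count: float = 2.5e11    # platelets per liter
    reference_concentration: float = 10.0  # model units (total platelet conc., nM)

    def __post_init__(self):
        if not (0 <= self.release_fraction <= 1):
            raise ValueError("release_fraction must lie in [0, 1]")
        for name in ("adp_content", "polyp_content", "platelet_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpeciesState:
    """Nodal concentration fields (nM) at one time instant."""

    mesh: Mesh
    rp: np.ndarray
    ap: np.ndarray
    adp: np.ndarray
    polyp: np.ndarray
    time: float = 0.0

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            self.mesh, self.rp.copy(), self.ap.copy(), self.adp.copy(),
            self.polyp.copy(), self.time,
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"RP": self.rp, "AP": self.ap, "ADP": self.adp, "PolyP": self.polyp}


def _ramp(x, lo: float, hi: float):
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def shear_activation_fraction(srcum, params: KineticParameters | None = None):
    """Ramp f(SRcum): 0 up to srcum_lo, linear to 1 at srcum_hi."""
    params = params or KineticParameters()
    srcum = np.asarray(srcum, dtype=float)
    if np.any(srcum < 0):
        raise ValueError("cumulative shear rate must be non-negative")
    return _ramp(srcum, params.srcum_lo, params.srcum_hi)


def shear_activation_rate(srcum, params: KineticParameters | None = None):
    """Mechanical activation rate A(SRcum) = k_AP_SR * f(SRcum), s^-1."""
    params = params or KineticParameters()
    return params.k_AP_SR * shear_activation_fraction(srcum, params)


def adp_activation_fraction(adp, params: KineticParameters | None = None):
    """Ramp f([ADP]): 0 below 0.2 uM, 1 above 1 uM (defaults, in nM)."""
    params = params or KineticParameters()
    adp = np.asarray(adp, dtype=float)
    if np.any(adp < 0):
        raise ValueError("ADP concentration must be non-negative")
    return _ramp(adp, params.adp_lo, params.adp_hi)


def released_coefficient(contents: GranuleContents, which: str) -> float:
    """Dimensionless agonist release ratio from granule stoichiometry.

    release_fraction * content[mol / 1e17 plt] * platelet_count[plt/l]
    expressed in nmol/l, divided by the reference platelet concentration in
    the same (model nM) units.  Defaults give 562.5 for ADP, 138.75 for PolyP.
    """
    if contents.reference_concentration == 0:
        raise ValueError("reference concentration must be non-zero")
    content = {"ADP": contents.adp_content, "PolyP": contents.polyp_content}[which]
    released_nM = (
        contents.release_fraction * content * contents.platelet_count / 1e17 * 1e9
    )
    return released_nM / contents.reference_concentration


def activation_rates(
    rp, ap, adp, srcum, params: KineticParameters | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(biochemical, mechanical, thrombin) activation rates, nM/s."""
    params = params or KineticParameters()
    rp = np.asarray(rp, dtype=float)
    bio = params.k_AP_AP * adp_activation_fraction(adp, params) * np.asarray(ap, float) * rp
    mech = shear_activation_rate(srcum, params) * rp
    thrombin = params.k_AP_IIa * rp
    return bio, mech, thrombin


def reaction_rates(
    state: SpeciesState,
    srcum_nodal: np.ndarray,
    params: KineticParameters | None = None,
) -> dict[str, np.ndarray]:
    """Per-species reaction rates (nM/s) on the state's mesh.

    R_RP = -S, R_AP = +S, R_ADP = ADP_rel * S, R_PolyP = PolyP_rel * S,
    where S sums the three activation channels; R_RP + R_AP = 0 identically.
    """
    params = params or KineticParameters()
    srcum_nodal = np.asarray(srcum_nodal, dtype=float)
    if srcum_nodal.shape != state.rp.shape:
        raise ValueError("cumulative shear field does not match the species mesh")
    bio, mech, thrombin = activation_rates(state.rp, state.ap, state.adp, srcum_nodal, params)
    S = bio + mech + thrombin
    return {
        "RP": -S,
        "AP": S,
        "ADP": params.ADP_rel * S,
        "PolyP": params.PolyP_rel * S,
    }


def _rhs(y: np.ndarray, srcum: float, params: KineticParameters) -> np.ndarray:
    rp, ap, adp, polyp = np.maximum(y, 0.0)
    bio, mech, thrombin = activation_rates(rp, ap, adp, srcum, params)
    S = bio + mech + thrombin
    return np.array([-S, S, params.ADP_rel * S, params.PolyP_rel * S])


def wellmixed_evolve(
    initial: dict[str, float] | np.ndarray,
    srcum: float,
    params: KineticParameters | None = None,
    t_end: float = 10.0,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """High-accuracy 0D (well-mixed) solution of the reaction ODEs.

    Returns (times, y) with y of shape (n, 4) ordered RP, AP, ADP, PolyP.
    Serves as the oracle for the spatial solver in the zero-velocity limit.
    """
    params = params or KineticParameters()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if isinstance(initial, dict):
        y0 = np.array([initial["RP"], initial["AP"], initial["ADP"], initial["PolyP"]], float)
    else:
        y0 = np.asarray(initial, dtype=float)
    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(
        lambda t, y: _rhs(y, srcum, params),
        (0.0, t_eval[-1]),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    return sol.t, sol.y.T
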