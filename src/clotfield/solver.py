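"""Stabilized finite-element solver for the reaction-advection-diffusion system.

The four species concentrations satisfy

    dA/dt + div(u A) - D laplace(A) = R(A),

discretized with linear (P1) triangles, SUPG streamline stabilization, a
theta time scheme (backward Euler by default), and first-order operator
splitting for the reactions (an explicit RK4 sub-step of the local kinetics
after each implicit transport solve).  Boundary conditions: Dirichlet at the
inlet (circulating values), natural no-flux on walls and free (zero diffusive
flux) outflow at the outlet.  The cumulative-shear-rate field driving the
mechanical activation term is precomputed by the Lagrangian module and frozen
during the solve (one-way coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .flow import FlowCase, TimePeriodicVelocityField
from .kinetics import KineticParameters, SpeciesState, activation_rates
from .lagrangian import CumulativeShearField
from .mesh import INLET, Mesh

SPECIES = ("RP", "AP", "ADP", "PolyP")

TABLE_DEFAULTS = {"RP": 10.0, "AP": 0.5, "ADP": 250.0, "PolyP": 0.0}  # nM
DIFFUSIVITY_DEFAULTS = {"RP": 1e-7, "AP": 1e-7, "ADP": 25.7e-7, "PolyP": 1e-7}  # cm^2/s


@dataclass
class RADConfig:
    """Solver settings; dt defaults to T/200 when omitted."""

    dt: float | None = None
    n_cycles: int = 10
    diffusivities: dict[str, float] = dc_field(
        default_factory=lambda: dict(DIFFUSIVITY_DEFAULTS)
    )
    supg: bool = True
    conservative: bool = False
    mass_lumping: bool = False
    clip_negative: bool = True
    theta: float = 1.0
    snapshots_per_cycle: int = 1

    def __post_init__(self):
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(d < 0 for d in self.diffusivities.values()):
            raise ValueError("diffusivities must be non-negative")


@dataclass
class BoundarySpec:
    """Inlet Dirichlet values (nM); walls no-flux; outlet free outflow."""

    inlet_values: dict[str, float] = dc_field(default_factory=lambda: dict(TABLE_DEFAULTS))
    inlet_dirichlet: bool = True

    def __post_init__(self):
        if any(v < 0 for v in self.inlet_values.values()):
            raise ValueError("inlet values must be non-negative")


def initialize_state(mesh: Mesh, values: dict[str, float] | None = None) -> SpeciesState:
    """Uniform circulating-concentration initial state (Table defaults)."""
    if len(mesh.nodes) == 0:
        raise ValueError("mesh has no nodes")
    vals = dict(TABLE_DEFAULTS)
    if values:
        vals.update(values)
    if any(v < 0 for v in vals.values()):
        raise ValueError("initial concentrations must be non-negative")
    n = len(mesh.nodes)
    return SpeciesState(
        mesh,
        np.full(n, vals["RP"]),
        np.full(n, vals["AP"]),
        np.full(n, vals["ADP"]),
        np.full(n, vals["PolyP"]),
        time=0.0,
    )


@dataclass
class TransportOperator:
    """Assembled P1+SUPG matrices: generalized mass and transport."""

    mass: sp.csr_matrix        # consistent mass + SUPG mass
    transport: sp.csr_matrix   # advection (conservative) + SUPG + D * stiffness


def _element_matrices(mesh: Mesh, u_nodal: np.ndarray | None, D: float,
                      supg: bool, dt_for_tau: float | None,
                      conservative: bool = False, mass_lumping: bool = False):
    """(M, 3, 3) element matrices: mass-like and transport-like.

    The advective form u . grad A is the default: the continuum fields are
    divergence-free, and the conservative form div(u A) turns the O(h)
    divergence of the interpolated velocity into a spurious local
    growth/decay rate that compounds over long runs.
    """
    areas = mesh.element_measures
    if np.any(areas <= 0):
        raise ValueError("zero-measure element in mesh")
    g = mesh.shape_gradients                        # (M, 3, 2)
    M = len(mesh.elements)
    eye = np.eye(3)
    Mc = areas[:, None, None] * (np.ones((3, 3)) + eye) / 12.0

    K = areas[:, None, None] * np.einsum("mia,mja->mij", g, g)

    if u_nodal is None:
        ue = np.zeros((M, 3, 2))
    else:
        ue = u_nodal[mesh.elements]                 # (M, 3, 2)
    usum = ue.sum(axis=1)
    ubar = usum / 3.0
    # conservative advection: int phi_i div(u_h phi_j)
    w = (areas[:, None, None] / 12.0) * (usum[:, None, :] + ue)     # (M, 3, 2)
    C = np.einsum("mia,mja->mij", w, g)
    div = np.einsum("mka,mka->m", ue, g)
    if conservative:
        C += div[:, None, None] * Mc
    else:
        div = np.zeros_like(div)

    Msupg = np.zeros_like(Mc)
    Csupg = np.zeros_like(Mc)
    if supg:
        speed = np.linalg.norm(ubar, axis=1)
        h = np.sqrt(4.0 * areas / np.sqrt(3.0))
        terms = (2.0 * speed / h) ** 2 + (4.0 * D / h**2) ** 2
        if dt_for_tau is not None:
            terms = terms + (2.0 / dt_for_tau) ** 2
        with np.errstate(divide="ignore"):
            tau = np.where(terms > 0, 1.0 / np.sqrt(np.maximum(terms, 1e-300)), 0.0)
        adv_i = np.einsum("ma,mia->mi", ubar, g)            # ubar . grad phi_i
        p = tau[:, None] * adv_i                            # (M, 3)
        Msupg = p[:, :, None] * (areas[:, None, None] / 3.0)
        Csupg = areas[:, None, None] * np.einsum("mi,mj->mij", p, adv_i)
        Csupg += (div * areas / 3.0)[:, None, None] * p[:, :, None]

    if mass_lumping:
        # lump the symmetric Galerkin mass (improves monotonicity of the
        # implicit advection step); the SUPG mass term stays consistent
        lump = np.zeros_like(Mc)
        rs = Mc.sum(axis=2)
        for i in range(3):
            lump[:, i, i] = rs[:, i]
        Mc = lump
    return Mc + Msupg, C + Csupg + D * K


def assemble_transport(
    mesh: Mesh,
    field: TimePeriodicVelocityField | None,
    D: float,
    time: float,
    supg: bool = True,
    dt_for_tau: float | None = None,
    conservative: bool = False,
    mass_lumping: bool = False,
) -> TransportOperator:
    """Assemble the P1 Galerkin + SUPG advection-diffusion operator at a time."""
    u_nodal = field.frame_at(time) if field is not None else None
    Me, Te = _element_matrices(mesh, u_nodal, D, supg, dt_for_tau, conservative,
                               mass_lumping)
    n = len(mesh.nodes)
    rows = np.repeat(mesh.elements, 3, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 3)).ravel()
    mass = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    transport = sp.coo_matrix((Te.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return TransportOperator(mass, transport)


class TransportStepper:
    """Caches assembled/factorized systems keyed by cycle phase and D."""

    def __init__(self, mesh: Mesh, field, period: float | None, config: RADConfig,
                 dirichlet_nodes: np.ndarray):
        self.mesh = mesh
        self.field = field
        self.period = period
        self.config = config
        self.dirichlet = dirichlet_nodes
        self._cache: dict = {}

    def _system(self, t_new: float, D: float, dt: float):
        phase = round(t_new % self.period, 10) if (self.field is not None and self.period) else 0.0
        key = (phase, D, dt)
        if key not in self._cache:
            op = assemble_transport(
                self.mesh, self.field, D, t_new, supg=self.config.supg,
                dt_for_tau=dt, conservative=self.config.conservative,
                mass_lumping=self.config.mass_lumping,
            )
            theta = self.config.theta
            lhs = (op.mass / dt + theta * op.transport).tolil()
            rhs_mat = (op.mass / dt - (1.0 - theta) * op.transport).tocsr()
            if len(self.dirichlet):
                lhs[self.dirichlet, :] = 0.0
                lhs[self.dirichlet, self.dirichlet] = 1.0
            if len(self._cache) > 900:
                self._cache.clear()
            self._cache[key] = (splu(lhs.tocsc()), rhs_mat)
        return self._cache[key]

    def transport_step(
        self,
        a: np.ndarray,
        t_old: float,
        dt: float,
        D: float,
        dirichlet_values: float | np.ndarray | None,
        source: np.ndarray | None = None,
    ) -> np.ndarray:
        lu, rhs_mat = self._system(t_old + dt, D, dt)
        rhs = rhs_mat @ a
        if source is not None:
            rhs = rhs + source
        if len(self.dirichlet) and dirichlet_values is not None:
            rhs[self.dirichlet] = dirichlet_values
        return lu.solve(rhs)


def _reaction_substep(y: np.ndarray, srcum: np.ndarray, params: KineticParameters,
                      dt: float) -> np.ndarray:
    """RK4 step of the local kinetics; y is (4, N) ordered as SPECIES."""

    def f(yy):
        rp, ap, adp = np.maximum(yy[0], 0.0), np.maximum(yy[1], 0.0), np.maximum(yy[2], 0.0)
        bio, mech, thrombin = activation_rates(rp, ap, adp, srcum, params)
        S = bio + mech + thrombin
        return np.stack([-S, S, params.ADP_rel * S, params.PolyP_rel * S])

    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


@dataclass
class RunLog:
    cycle_extrema: list
    clipped_mass: float = 0.0


def advance(
    state: SpeciesState,
    stepper: TransportStepper,
    params: KineticParameters,
    srcum_nodal: np.ndarray,
    dt: float,
    boundary: BoundarySpec,
    config: RADConfig,
    log: RunLog | None = None,
) -> SpeciesState:
    """One time step: implicit transport per species, then reaction sub-step."""
    arrays = state.as_dict()
    new = {}
    for name in SPECIES:
        a = arrays[name]
        bc_val = boundary.inlet_values[name] if boundary.inlet_dirichlet else None
        a_new = stepper.transport_step(
            a, state.time, dt, config.diffusivities[name], bc_val
        )
        if np.any(np.isnan(a_new)):
            raise RuntimeError(
                f"NaN detected in species {name} at t={state.time + dt:.6g}"
            )
        new[name] = a_new
    y = np.stack([new[n] for n in SPECIES])
    y = _reaction_substep(y, srcum_nodal, params, dt)
    if config.clip_negative:
        if log is not None:
            lumped = _lumped_mass(state.mesh)
            log.clipped_mass += float(np.sum(np.clip(-y, 0.0, None) * lumped[None, :]))
        y = np.maximum(y, 0.0)
    return SpeciesState(state.mesh, y[0], y[1], y[2], y[3], time=state.time + dt)


def _lumped_mass(mesh: Mesh) -> np.ndarray:
    lumped = np.zeros(len(mesh.nodes))
    np.add.at(lumped, mesh.elements.ravel(),
              np.repeat(mesh.element_measures / 3.0, 3))
    return lumped


def integrate_total(mesh: Mesh, nodal: np.ndarray) -> float:
    """Domain integral of a nodal field (lumped quadrature)."""
    return float(np.sum(_lumped_mass(mesh) * nodal))


def run_simulation(
    case: FlowCase,
    srcum_field: CumulativeShearField | np.ndarray | None,
    params: KineticParameters | None = None,
    config: RADConfig | None = None,
    boundary: BoundarySpec | None = None,
    initial: SpeciesState | None = None,
) -> tuple[list[SpeciesState], RunLog]:
    """Integrate the RAD system for config.n_cycles cardiac cycles.

    Returns snapshots (initial state plus ``snapshots_per_cycle`` per cycle)
    and a run log with per-cycle extrema and total clipped mass.
    """
    params = params or KineticParameters()
    config = config or RADConfig()
    boundary = boundary or BoundarySpec()
    mesh = case.mesh
    T = case.period

    if srcum_field is None:
        srcum_nodal = np.zeros(len(mesh.nodes))
    elif isinstance(srcum_field, CumulativeShearField):
        srcum_nodal = srcum_field.nodal(mesh)
    else:
        srcum_nodal = np.asarray(srcum_field, dtype=float)
        if srcum_nodal.shape != (len(mesh.nodes),):
            raise ValueError("srcum field shape does not match the mesh")

    state = initial.copy() if initial is not None else initialize_state(mesh)
    if config.n_cycles == 0:
        return [state], RunLog(cycle_extrema=[])

    steps_per_cycle = int(round(T / config.dt)) if config.dt else 200
    dt = T / steps_per_cycle
    snap_every = max(1, steps_per_cycle // config.snapshots_per_cycle)

    dirichlet = mesh.nodes_on(INLET) if boundary.inlet_dirichlet else np.array([], dtype=int)
    stepper = TransportStepper(mesh, case.field, T, config, dirichlet)
    log = RunLog(cycle_extrema=[])
    snapshots = [state.copy()]

    for cycle in range(config.n_cycles):
        for s in range(steps_per_cycle):
            state = advance(state, stepper, params, srcum_nodal, dt, boundary, config, log)
            if (s + 1) % snap_every == 0:
                snapshots.append(state.copy())
        ext = {
            name: (float(arr.min()), float(arr.max()))
            for name, arr in state.as_dict().items()
        }
        log.cycle_extrema.append(ext)
    return snapshots, log


def peclet_number(case: FlowCase, D: float, length_scale: float) -> float:
    """Pe = U_char * L / D with U_char the cycle- and space-averaged speed."""
    if length_scale <= 0:
        raise ValueError("length scale must be positive")
    U = case.field.mean_speed()
    if D == 0:
        return np.inf if U > 0 else 0.0
    return U * length_scale / D
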