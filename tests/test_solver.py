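"""Transport solver oracles: heat kernel, advection, MMS convergence, 0D limit."""

import numpy as np
import pytest

import clotfield as cf
from clotfield.flow import FlowCase
from clotfield.kinetics import KineticParameters, wellmixed_evolve
from clotfield.mesh import INLET, OUTLET, build_channel_mesh
from clotfield.solver import (
    BoundarySpec,
    RADConfig,
    TransportStepper,
    _lumped_mass,
    initialize_state,
    integrate_total,
    peclet_number,
    run_simulation,
)

from conftest import make_constant_field

NO_REACTION = KineticParameters(k_AP_AP=0.0, k_AP_SR=0.0, k_AP_IIa=0.0)


def make_stepper(mesh, field, period, dirichlet_nodes, **cfg):
    config = RADConfig(**cfg)
    return TransportStepper(mesh, field, period, config, dirichlet_nodes)


class TestInitialState:
    def test_defaults_give_five_percent_activation(self, channel_mesh):
        s = initialize_state(channel_mesh)
        ratio = s.ap[0] / (s.rp[0] + s.ap[0])
        assert ratio == pytest.approx(0.5 / 10.5, rel=1e-12)  # ~4.76%
        assert np.all(s.adp == 250.0) and np.all(s.polyp == 0.0)

    def test_override(self, channel_mesh):
        s = initialize_state(channel_mesh, {"PolyP": 5.0})
        assert np.all(s.polyp == 5.0)

    def test_negative_override_rejected(self, channel_mesh):
        with pytest.raises(ValueError):
            initialize_state(channel_mesh, {"ADP": -1.0})

    def test_empty_mesh_rejected(self):
        from clotfield.mesh import Mesh

        empty = Mesh(np.zeros((0, 2)), np.zeros((0, 3), int),
                     np.zeros((0, 2), int), np.array([]))
        with pytest.raises(ValueError):
            initialize_state(empty)


class TestTransportOracles:
    def test_constant_state_preserved(self, control_case):
        """Uniform state with matching inlet Dirichlet stays constant."""
        cfg = RADConfig(dt=control_case.period / 50, n_cycles=1)
        snaps, _ = run_simulation(control_case, None, NO_REACTION, cfg, BoundarySpec())
        final, first = snaps[-1], snaps[0]
        for name in ("rp", "ap", "adp", "polyp"):
            a, b = getattr(final, name), getattr(first, name)
            assert np.max(np.abs(a - b)) < 1e-10 * max(1.0, np.max(np.abs(b)))

    def test_pure_diffusion_matches_heat_kernel(self):
        """1D Gaussian spreading under D with u=0, against the closed form."""
        mesh = build_channel_mesh(4.0, 0.2, 0.05)
        D, sig0, x0, t_end, dt = 0.01, 0.4, 2.0, 2.0, 0.01
        a = np.exp(-((mesh.nodes[:, 0] - x0) ** 2) / (2 * sig0**2))
        stepper = make_stepper(mesh, None, None, np.array([], dtype=int), dt=dt)
        t = 0.0
        while t < t_end - 1e-12:
            a = stepper.transport_step(a, t, dt, D, None)
            t += dt
        sig = np.sqrt(sig0**2 + 2 * D * t_end)
        exact = (sig0 / sig) * np.exp(-((mesh.nodes[:, 0] - x0) ** 2) / (2 * sig**2))
        assert a.max() == pytest.approx(sig0 / sig, rel=0.02)
        assert np.max(np.abs(a - exact)) < 0.02 * (sig0 / sig)

    def test_advection_of_gaussian_pulse(self):
        """D=0, uniform u: peak moves u*t within one element; decay < 5%."""
        mesh = build_channel_mesh(6.0, 0.2, 0.05)
        u, sig0, x0, t_end, dt = 2.0, 0.5, 1.5, 1.0, 0.001
        field = make_constant_field(mesh, (u, 0.0), period=1.0)
        a = np.exp(-((mesh.nodes[:, 0] - x0) ** 2) / (2 * sig0**2))
        inlet = mesh.nodes_on(INLET)
        stepper = make_stepper(mesh, field, 1.0, inlet, dt=dt)
        t = 0.0
        while t < t_end - 1e-9:
            a = stepper.transport_step(a, t, dt, 0.0, 0.0)
            t += dt
        peak = mesh.nodes[np.argmax(a), 0]
        assert abs(peak - (x0 + u * t_end)) <= 0.05 + 1e-9
        assert a.max() > 0.95

    def test_manufactured_solution_convergence(self):
        """A = sin(kx) e^(-t) with a forcing term: L2 error falls with h."""
        k, u, D, t_end = np.pi, 1.0, 1e-3, 0.25
        errors = []
        for res in (0.25, 0.125, 0.0625):
            mesh = build_channel_mesh(2.0, 0.25, res)
            dt = 0.02 * (res / 0.25) ** 2
            field = make_constant_field(mesh, (u, 0.0), period=1.0)
            x = mesh.nodes[:, 0]
            dirichlet = np.union1d(mesh.nodes_on(INLET), mesh.nodes_on(OUTLET))
            stepper = make_stepper(mesh, field, 1.0, dirichlet, dt=dt)
            lumped = _lumped_mass(mesh)
            a = np.sin(k * x)
            t = 0.0
            while t < t_end - 1e-12:
                tn = t + dt
                f = np.exp(-tn) * (-np.sin(k * x) + u * k * np.cos(k * x)
                                   + D * k**2 * np.sin(k * x))
                a = stepper.transport_step(a, t, dt, D, 0.0, source=lumped * f)
                t = tn
            exact = np.sin(k * x) * np.exp(-t_end)
            errors.append(np.sqrt(np.sum(lumped * (a - exact) ** 2)))
        assert errors[0] > errors[1] > errors[2]

    def test_maximum_principle_without_reactions(self):
        """Resolved transport without reactions stays in the data range (+1%).

        Uniform advection of a smooth bump with inlet Dirichlet equal to the
        background; SUPG keeps over/undershoots below 1% of the bump height.
        (In shear flow with no-slip walls the scheme is not monotone --
        a documented limitation, not tested here.)
        """
        mesh = build_channel_mesh(4.0, 0.2, 0.05)
        field = make_constant_field(mesh, (20.0, 0.0), period=1.0)
        case = FlowCase(mesh, field, 1.0)
        init = initialize_state(mesh)
        bump = 500.0 * np.exp(
            -((mesh.nodes[:, 0] - 1.0) ** 2 + mesh.nodes[:, 1] ** 2) / (2 * 0.25**2)
        )
        init.adp = init.adp + bump
        hi = init.adp.max()
        cfg = RADConfig(dt=0.004, n_cycles=2, snapshots_per_cycle=8,
                        clip_negative=False)
        snaps, _ = run_simulation(case, None, NO_REACTION, cfg,
                                  BoundarySpec(), initial=init)
        for s in snaps:
            assert s.adp.max() <= hi + 0.01 * (hi - 250.0)
            assert s.adp.min() >= 250.0 - 0.01 * (hi - 250.0)


@pytest.fixture(scope="module")
def quiet_case():
    mesh = build_channel_mesh(0.5, 0.1, 0.05)
    field = make_constant_field(mesh, (0.0, 0.0), period=1.0)
    return FlowCase(mesh, field, 1.0, label="closed-box")


class TestZeroDimensionalLimit:

    def test_matches_wellmixed_oracle(self, quiet_case):
        """u=0, D=0: the PDE solver must reproduce the 0D kinetics to 1%."""
        cfg = RADConfig(dt=0.01, n_cycles=10,
                        diffusivities={k: 0.0 for k in ("RP", "AP", "ADP", "PolyP")})
        srcum = np.full(len(quiet_case.mesh.nodes), 600.0)
        snaps, _ = run_simulation(quiet_case, srcum, KineticParameters(), cfg,
                                  BoundarySpec(inlet_dirichlet=False))
        t, y = wellmixed_evolve({"RP": 10, "AP": 0.5, "ADP": 250, "PolyP": 0},
                                srcum=600.0, t_end=10.0, dt=0.01)
        final = snaps[-1]
        scale = {"rp": 10.5, "ap": 10.5, "adp": y[-1, 2], "polyp": y[-1, 3]}
        for i, name in enumerate(("rp", "ap", "adp", "polyp")):
            got = getattr(final, name)[0]
            assert got == pytest.approx(y[-1, i], abs=0.01 * scale[name])

    def test_closed_box_platelet_conservation(self, quiet_case):
        cfg = RADConfig(dt=0.01, n_cycles=8)
        srcum = np.full(len(quiet_case.mesh.nodes), 400.0)
        snaps, _ = run_simulation(quiet_case, srcum, KineticParameters(), cfg,
                                  BoundarySpec(inlet_dirichlet=False))
        mesh = quiet_case.mesh
        tot0 = integrate_total(mesh, snaps[0].rp + snaps[0].ap)
        for s in snaps:
            tot = integrate_total(mesh, s.rp + s.ap)
            assert tot == pytest.approx(tot0, rel=1e-3)

    def test_agonist_stoichiometry(self, quiet_case):
        cfg = RADConfig(dt=0.01, n_cycles=8)
        srcum = np.full(len(quiet_case.mesh.nodes), 400.0)
        snaps, _ = run_simulation(quiet_case, srcum, KineticParameters(), cfg,
                                  BoundarySpec(inlet_dirichlet=False))
        mesh = quiet_case.mesh
        d_ap = integrate_total(mesh, snaps[-1].ap) - integrate_total(mesh, snaps[0].ap)
        d_adp = integrate_total(mesh, snaps[-1].adp) - integrate_total(mesh, snaps[0].adp)
        d_polyp = integrate_total(mesh, snaps[-1].polyp)
        assert d_adp == pytest.approx(562.5 * d_ap, rel=0.01)
        assert d_polyp == pytest.approx(138.75 * d_ap, rel=0.01)


class TestRunControl:
    def test_zero_cycles_returns_initial(self, control_case):
        snaps, log = run_simulation(control_case, None, config=RADConfig(n_cycles=0))
        assert len(snaps) == 1 and snaps[0].time == 0.0
        assert log.cycle_extrema == []

    def test_snapshot_cadence_and_extrema(self, control_case):
        cfg = RADConfig(dt=control_case.period / 20, n_cycles=2, snapshots_per_cycle=2)
        snaps, log = run_simulation(control_case, None, NO_REACTION, cfg)
        assert len(snaps) == 5
        assert len(log.cycle_extrema) == 2
        assert set(log.cycle_extrema[0]) == {"RP", "AP", "ADP", "PolyP"}


class TestPeclet:
    def test_macroscale_value(self, channel_mesh):
        field = make_constant_field(channel_mesh, (10.0, 0.0))
        case = FlowCase(channel_mesh, field, 1.0)
        assert peclet_number(case, 1e-7, 0.3) == pytest.approx(3e7, rel=1e-9)
        assert peclet_number(case, 1e-7, 0.3) > 1e3

    def test_platelet_microscale_marginal(self, channel_mesh):
        field = make_constant_field(channel_mesh, (1e-3, 0.0))
        case = FlowCase(channel_mesh, field, 1.0)
        assert peclet_number(case, 1e-7, 2e-4) == pytest.approx(2.0, rel=1e-9)

    def test_degenerate_inputs(self, channel_mesh):
        moving = FlowCase(channel_mesh, make_constant_field(channel_mesh, (1.0, 0.0)), 1.0)
        still = FlowCase(channel_mesh, make_constant_field(channel_mesh, (0.0, 0.0)), 1.0)
        assert peclet_number(moving, 0.0, 0.3) == np.inf
        assert peclet_number(still, 1e-7, 0.3) == 0.0
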