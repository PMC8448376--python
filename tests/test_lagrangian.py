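"""Pathline tracking oracles: strain rate, transit times, cumulative shear."""

import numpy as np
import pytest

import clotfield as cf
from clotfield import lagrangian as lg
from clotfield.mesh import build_channel_mesh

from conftest import make_constant_field

H = 0.15
U = 10.0
L = 2.0
T = 0.8


def row_midspans(mesh):
    """y midpoints of the structured rows (where the P1 gradient is exact)."""
    ys = np.unique(np.round(mesh.nodes[:, 1], 12))
    return 0.5 * (ys[:-1] + ys[1:])


class TestStrainRate:
    def test_uniform_translation_zero(self, channel_mesh):
        f = make_constant_field(channel_mesh, (3.0, 1.0))
        E = lg.strain_rate_tensor(f, np.array([1.0, 0.05]), 0.0)
        assert np.allclose(E, 0.0, atol=1e-12)
        assert lg.shear_rate(f, np.array([1.0, 0.05]), 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_zero(self, channel_mesh):
        frames = np.zeros((4, len(channel_mesh.nodes), 2))
        frames[:, :, 0] = -channel_mesh.nodes[:, 1]
        frames[:, :, 1] = channel_mesh.nodes[:, 0]
        f = cf.TimePeriodicVelocityField(channel_mesh, frames, 1.0, np.arange(4) / 4.0)
        E = lg.strain_rate_tensor(f, np.array([1.0, 0.05]), 0.0)
        assert np.allclose(E, 0.0, atol=1e-10)

    def test_poiseuille_shear_components(self, steady_poiseuille):
        # E12 = E21 = -U y / h^2, E11 = E22 = 0; exact at row midspans
        for y in row_midspans(steady_poiseuille.mesh)[1:-1]:
            E = lg.strain_rate_tensor(steady_poiseuille, np.array([1.0, y]), 0.0)
            expected = -U * y / H**2
            assert E[0, 1] == pytest.approx(expected, rel=1e-9, abs=1e-9)
            assert E[1, 0] == pytest.approx(expected, rel=1e-9, abs=1e-9)
            assert abs(E[0, 0]) < 1e-9 and abs(E[1, 1]) < 1e-9

    def test_poiseuille_shear_rate_magnitude(self, steady_poiseuille):
        # SR = sqrt(2 (E12^2 + E21^2)) = 2 |U y / h^2|
        for y in row_midspans(steady_poiseuille.mesh)[1:-1]:
            sr = lg.shear_rate(steady_poiseuille, np.array([0.7, y]), 0.0)
            assert sr == pytest.approx(2 * U * abs(y) / H**2, rel=1e-9, abs=1e-9)

    def test_outside_domain_is_nan(self, steady_poiseuille):
        assert np.isnan(lg.shear_rate(steady_poiseuille, np.array([50.0, 0.0]), 0.0))


class TestSeeding:
    def test_one_seed_per_interior_inlet_node(self, channel_mesh):
        seeds = lg.seed_inlet(channel_mesh, period=T)
        inlet = channel_mesh.nodes_on("inlet")
        wallish = set(channel_mesh.nodes_on("wall"))
        interior = [n for n in inlet if n not in wallish]
        assert len(seeds.points) == len(interior)
        assert np.allclose(seeds.release_times, [0, T / 4, T / 2, 3 * T / 4])
        # seeds sit just inside the domain
        assert np.all(channel_mesh.locate(seeds.points) >= 0)

    def test_custom_release_times(self, channel_mesh):
        seeds = lg.seed_inlet(channel_mesh, release_times=[0.0])
        assert list(seeds.release_times) == [0.0]

    def test_missing_inlet_rejected(self, channel_mesh):
        m = build_channel_mesh(1.0, 0.1, 0.05)
        m.facet_tags = np.array(["wall"] * len(m.facet_tags))
        with pytest.raises(ValueError, match="inlet"):
            lg.seed_inlet(m, period=T)


class TestIntegration:
    def test_transit_time_matches_analytic(self, steady_poiseuille):
        """Seed on a node row (exact nodal velocity): transit = L / u(y0)."""
        y0 = -0.10  # node row of the 0.05-resolution channel
        p = lg.integrate_pathline(steady_poiseuille, np.array([1e-9, y0]), 0.0, dt=T / 1000)
        assert p.termination == "outlet"
        u = U * (1 - (y0 / H) ** 2)
        assert p.times[-1] - p.times[0] == pytest.approx(L / u, rel=1e-3)
        # transverse coordinate is conserved in parallel flow
        assert abs(p.positions[-1, 1] - y0) < 1e-8 * H

    def test_cumulative_shear_closed_form(self, steady_poiseuille):
        """Constant-SR pathline: SRcum = SR(y0) * transit (seed at row midspan)."""
        y0 = row_midspans(steady_poiseuille.mesh)[1]
        p = lg.integrate_pathline(steady_poiseuille, np.array([1e-9, y0]), 0.0, dt=T / 1000)
        sr = 2 * U * abs(y0) / H**2
        transit = p.times[-1] - p.times[0]
        assert p.srcum[-1] == pytest.approx(sr * transit, rel=5e-3)

    def test_stagnation_seed_terminates_stagnant(self):
        mesh = cf.build_aneurysm_mesh(0.15, 0.4, 1.0, 1.5, 1.0, 0.05)
        # uniform modulation (equal amplitudes, no lag): the vortex center is
        # an exact stagnation point at all times
        f = cf.make_recirculating_field(
            mesh, 4.0, 0.5, T, 20,
            pulsatility_amplitude=0.2, vortex_pulsatility=0.2, vortex_phase_lag=0.0,
        )
        p = lg.integrate_pathline(f, f.stagnation_point, 0.0, dt=T / 200)
        assert p.termination == "stagnation"
        assert p.times[-1] - p.times[0] <= 1.5 * T  # detected after ~one cycle

    def test_dt_precondition(self, steady_poiseuille):
        with pytest.raises(ValueError, match="dt"):
            lg.integrate_pathline(steady_poiseuille, np.array([0.0, 0.0]), 0.0, dt=T)

    def test_determinism(self, steady_poiseuille):
        a = lg.integrate_pathline(steady_poiseuille, np.array([1e-9, 0.025]), 0.0, dt=T / 500)
        b = lg.integrate_pathline(steady_poiseuille, np.array([1e-9, 0.025]), 0.0, dt=T / 500)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.srcum, b.srcum)


class TestCumulativeShear:
    def test_single_sample_is_zero(self):
        assert list(lg.cumulative_shear([0.0], [5.0])) == [0.0]

    def test_constant_sr_closed_form(self):
        times = np.arange(0.0, 2.0 + 1e-12, 0.01)
        sr = np.full(len(times), 100.0)
        out = lg.cumulative_shear(times, sr)
        assert out[-1] == pytest.approx(200.0, rel=0.01)

    def test_monotone_on_fixture_pathlines(self, aneurysm_tracking, control_tracking):
        for p in aneurysm_tracking.pathlines + control_tracking.pathlines:
            assert p.srcum[0] == 0.0
            assert np.all(np.diff(p.srcum) >= -1e-14)
            assert np.all(p.sr[np.isfinite(p.sr)] >= 0)
            assert np.all(np.diff(p.times) > 0)


class TestReconstruction:
    def test_two_pathlines_average(self, channel_mesh):
        c = channel_mesh.element_centroids[10]
        mk = lambda v: lg.Pathline(
            np.array([0.0]), c[None, :], np.array([0.0]), np.array([v]), "outlet"
        )
        f = lg.reconstruct_cumulative_field([mk(2.0), mk(6.0)], channel_mesh)
        assert f.element_mean[10] == pytest.approx(4.0)
        assert f.sample_counts[10] == 2

    def test_single_stationary_pathline(self, channel_mesh):
        c = channel_mesh.element_centroids[3]
        p = lg.Pathline(np.array([0.0]), c[None, :], np.array([0.0]), np.array([7.0]), "stagnation")
        f = lg.reconstruct_cumulative_field([p], channel_mesh)
        assert f.element_mean[3] == pytest.approx(7.0)
        assert np.isnan(np.delete(f.element_mean, 3)).all()

    def test_control_channel_linear_growth(self, control_case, control_tracking):
        """Mean SRcum grows linearly with axial distance (r^2 > 0.99)."""
        mesh = control_case.mesh
        f = control_tracking.srcum
        cx = np.round(mesh.element_centroids[:, 0], 9)
        xs, vals = [], []
        for x in np.unique(cx):
            sel = (cx == x) & (f.sample_counts > 0)
            if sel.any():
                w = f.sample_counts[sel]
                xs.append(x)
                vals.append(np.sum(f.element_mean[sel] * w) / np.sum(w))
        r = np.corrcoef(xs, vals)[0, 1]
        assert r * r > 0.99

    def test_empty_pathlines_rejected(self, channel_mesh):
        with pytest.raises(ValueError):
            lg.reconstruct_cumulative_field([], channel_mesh)


class TestResidence:
    def test_uniform_flow_band_transit(self, channel_mesh):
        """Residence per element column = column width / speed."""
        u = 2.0
        f = make_constant_field(channel_mesh, (u, 0.0), period=T, n_frames=4)
        p = lg.integrate_pathline(f, np.array([1e-9, 0.013]), 0.0, dt=T / 1000)
        res = lg.residence_time_field([p], channel_mesh)
        col = np.floor(channel_mesh.element_centroids[:, 0] / 0.05).astype(int)
        for c in range(2, col.max() - 1):
            sel = (col == c) & np.isfinite(res)
            col_time = np.nansum(res[sel])
            assert col_time == pytest.approx(0.05 / u, rel=0.1)

    def test_stagnation_zone_residence_exceeds_channel(
        self, aneurysm_case, aneurysm_tracking, control_tracking, control_case
    ):
        from clotfield.mesh import bulge_mask

        res_a = aneurysm_tracking.residence
        res_c = control_tracking.residence
        mask = bulge_mask(aneurysm_case.mesh)
        assert np.nanmax(res_a[mask]) > 10 * np.nanmedian(res_c)

    def test_empty_set_all_missing(self, channel_mesh):
        res = lg.residence_time_field([], channel_mesh)
        assert np.isnan(res).all()
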