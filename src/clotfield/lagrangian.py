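"""Lagrangian pathline tracking and cumulative shear-rate reconstruction.

Massless tracer particles (platelet surrogates, Stokes number << 1) are
released at the inlet and integrated through the time-periodic velocity field
with a classical fixed-step RK4 scheme.  Along each pathline the scalar shear
rate SR = sqrt(2 E:E) (E the rate-of-strain tensor of the P1-interpolated
velocity) is sampled, and the cumulative shear rate SRcum = sum SR * dt is
accumulated as a left-endpoint Riemann sum.  Per-element averaging of the
(position, SRcum) samples over all pathlines and release cohorts reconstructs
the mean cumulative-shear-rate field; the same binning yields a per-element
residence-time field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import TimePeriodicVelocityField
from .mesh import INLET, OUTLET, WALL, Mesh

TERMINATION_OUTLET = "outlet"
TERMINATION_STAGNATION = "stagnation"
TERMINATION_MAX_CYCLES = "max_cycles"


@dataclass
class SeedSet:
    """Inlet seed locations (cm) and release times (s) within one cycle."""

    points: np.ndarray
    release_times: np.ndarray


@dataclass
class Pathline:
    times: np.ndarray
    positions: np.ndarray
    sr: np.ndarray
    srcum: np.ndarray
    termination: str
    n_projections: int = 0


@dataclass
class CumulativeShearField:
    """Per-element mean SRcum; NaN where no pathline sample landed."""

    element_mean: np.ndarray
    sample_counts: np.ndarray
    release_times: np.ndarray

    def nodal(self, mesh: Mesh) -> np.ndarray:
        """Node values as the mean of incident sampled elements (0 if none)."""
        vals = np.zeros(len(mesh.nodes))
        wsum = np.zeros(len(mesh.nodes))
        ok = self.sample_counts > 0
        for e in np.nonzero(ok)[0]:
            for n in mesh.elements[e]:
                vals[n] += self.element_mean[e]
                wsum[n] += 1.0
        nz = wsum > 0
        vals[nz] /= wsum[nz]
        return vals


# ---------------------------------------------------------------------------
# shear rate
# ---------------------------------------------------------------------------

def _gradients_at(field: TimePeriodicVelocityField, tri: np.ndarray, time: float) -> np.ndarray:
    """(P, 2, 2) velocity gradients of the given elements at a time."""
    nodal = field.frame_at(time)
    vals = nodal[field.mesh.elements[tri]]              # (P, 3, 2)
    grads = field.mesh.shape_gradients[tri]             # (P, 3, 2)
    return np.einsum("pia,pib->pab", vals, grads)


def strain_rate_tensor(
    field: TimePeriodicVelocityField, point: np.ndarray, time: float
) -> np.ndarray:
    """Rate-of-strain tensor E = (grad u + grad u^T)/2, s^-1; NaN outside."""
    tri = field.mesh.locate(np.atleast_2d(point))
    if tri[0] < 0:
        return np.full((2, 2), np.nan)
    G = _gradients_at(field, tri[:1], time)[0]
    return 0.5 * (G + G.T)


def shear_rate(field: TimePeriodicVelocityField, point: np.ndarray, time: float) -> float:
    """Scalar shear rate SR = sqrt(2 E:E) >= 0; NaN outside the domain."""
    E = strain_rate_tensor(field, point, time)
    return float(np.sqrt(2.0 * np.sum(E * E)))


def _shear_rates(field: TimePeriodicVelocityField, points: np.ndarray, time: float) -> np.ndarray:
    """Vectorized SR at several points (NaN outside)."""
    pts = np.atleast_2d(points)
    tri = field.mesh.locate(pts)
    out = np.full(len(pts), np.nan)
    inside = tri >= 0
    if inside.any():
        G = _gradients_at(field, tri[inside], time)
        E = 0.5 * (G + np.swapaxes(G, 1, 2))
        out[inside] = np.sqrt(2.0 * np.einsum("pab,pab->p", E, E))
    return out


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_inlet(
    mesh: Mesh,
    release_times: np.ndarray | None = None,
    period: float | None = None,
) -> SeedSet:
    """One seed per interior inlet node; default cohorts at 0, T/4, T/2, 3T/4.

    Inlet nodes shared with wall facets (no-slip corners) are skipped, and
    seeds are nudged a relative 1e-6 into the domain along the inlet normal.
    """
    inlet_nodes = mesh.nodes_on(INLET)
    if len(inlet_nodes) == 0:
        raise ValueError("mesh has no inlet facets")
    wall_nodes = set(mesh.nodes_on(WALL)) | set(mesh.nodes_on(OUTLET))
    interior = np.array([n for n in inlet_nodes if n not in wall_nodes])
    if len(interior) == 0:
        raise ValueError("inlet has no interior nodes to seed")
    pts = mesh.nodes[interior].astype(float).copy()

    # inward normal of the inlet: normal of first inlet facet, oriented
    # toward the domain centroid
    f = mesh.boundary_facets[mesh.facet_tags == INLET][0]
    edge = mesh.nodes[f[1]] - mesh.nodes[f[0]]
    normal = np.array([-edge[1], edge[0]])
    normal /= np.linalg.norm(normal)
    centroid = mesh.nodes.mean(axis=0)
    if np.dot(normal, centroid - mesh.nodes[f[0]]) < 0:
        normal = -normal
    pts += 1e-6 * mesh.domain_diameter * normal

    if release_times is None:
        if period is None:
            raise ValueError("period is required for the default release times")
        release_times = np.array([0.0, 0.25, 0.5, 0.75]) * period
    return SeedSet(pts, np.asarray(release_times, dtype=float))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _nearest_boundary_tag(mesh: Mesh, point: np.ndarray) -> str:
    """Tag of the boundary facet closest to a point."""
    a = mesh.nodes[mesh.boundary_facets[:, 0]]
    b = mesh.nodes[mesh.boundary_facets[:, 1]]
    ab = b - a
    tt = np.einsum("fj,fj->f", point[None, :] - a, ab) / np.einsum("fj,fj->f", ab, ab)
    tt = np.clip(tt, 0.0, 1.0)
    proj = a + tt[:, None] * ab
    d = np.linalg.norm(proj - point[None, :], axis=1)
    return str(mesh.facet_tags[np.argmin(d)])


def _crossing_fraction(mesh: Mesh, x0: np.ndarray, x1: np.ndarray, iters: int = 40) -> float:
    """Bisect alpha in (0,1]: largest alpha with x0 + alpha (x1-x0) inside."""
    lo, hi = 0.0, 1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mesh.locate((x0 + mid * (x1 - x0))[None, :])[0] >= 0:
            lo = mid
        else:
            hi = mid
    return lo


def integrate_pathlines(
    field: TimePeriodicVelocityField,
    seed_points: np.ndarray,
    release_time: float,
    dt: float | None = None,
    max_cycles: int = 30,
    stagnation_tol: float | None = None,
    max_projections: int = 100,
) -> list[Pathline]:
    """Integrate one release cohort of pathlines (vectorized over seeds).

    Termination, first criterion satisfied: reaching the outlet (exit point
    and time clipped by bisection along the step), stagnation (path length
    over the trailing cardiac period below ``stagnation_tol``, default
    1e-3 of the domain diameter), or ``max_cycles`` periods.
    """
    mesh = field.mesh
    T = field.period
    if dt is None:
        dt = T / 1000.0
    if dt >= T / 10.0:
        raise ValueError("dt must be smaller than one tenth of the period")
    if stagnation_tol is None:
        stagnation_tol = 1e-3 * mesh.domain_diameter

    pts = np.atleast_2d(np.asarray(seed_points, dtype=float)).copy()
    P = len(pts)
    if np.any(mesh.locate(pts) < 0):
        raise ValueError("seed point outside the domain")

    window = max(1, int(round(T / dt)))
    n_max = int(np.ceil(max_cycles * T / dt))

    active = np.ones(P, dtype=bool)
    termination = np.array([TERMINATION_MAX_CYCLES] * P, dtype=object)
    projections = np.zeros(P, dtype=int)
    end_step = np.full(P, n_max, dtype=int)      # last recorded sample index
    exit_time = np.full(P, np.nan)
    exit_point = np.full((P, 2), np.nan)

    pos_hist = np.full((n_max + 1, P, 2), np.nan)
    sr_hist = np.full((n_max + 1, P), np.nan)
    pathlen = np.zeros((n_max + 1, P))

    pos_hist[0] = pts
    sr_hist[0] = _shear_rates(field, pts, release_time)

    x = pts
    for k in range(n_max):
        t = release_time + k * dt
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        xi = x[idx]

        k1, in1 = field.sample(xi, t)
        k2, in2 = field.sample(xi + 0.5 * dt * k1, t + 0.5 * dt)
        k3, in3 = field.sample(xi + 0.5 * dt * k2, t + 0.5 * dt)
        k4, in4 = field.sample(xi + dt * k3, t + dt)
        x_new = xi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ok = in1 & in2 & in3 & in4
        tri_new = np.full(len(idx), -1)
        if ok.any():
            tri_new[ok] = mesh.locate(x_new[ok])
        trouble = ~ok | (tri_new < 0)

        for j in np.nonzero(trouble)[0]:
            p = idx[j]
            x0 = xi[j]
            x1 = x0 + dt * k1[j]
            if mesh.locate(x1[None, :])[0] >= 0:
                # substage overshoot only: fall back to an Euler step
                x_new[j] = x1
                continue
            alpha = _crossing_fraction(mesh, x0, x1)
            cross = x0 + max(alpha, 1e-12) * (x1 - x0)
            tag = _nearest_boundary_tag(mesh, cross)
            if tag == OUTLET:
                active[p] = False
                termination[p] = TERMINATION_OUTLET
                end_step[p] = k + 1
                exit_time[p] = t + alpha * dt
                exit_point[p] = cross
                x_new[j] = cross
            else:
                projections[p] += 1
                if projections[p] > max_projections:
                    raise RuntimeError("tracking unstable, reduce dt")
                x_new[j] = x0 + 0.95 * alpha * (x1 - x0)

        step_len = np.linalg.norm(x_new - xi, axis=1)
        x[idx] = x_new
        pos_hist[k + 1, idx] = x_new
        pathlen[k + 1, idx] = pathlen[k, idx] + step_len
        # sample SR at accepted positions (exit points nudged back inside)
        sr = _shear_rates(field, x_new, t + dt)
        bad = np.isnan(sr)
        if bad.any():
            nudged = x_new[bad] + 1e-9 * (xi[bad] - x_new[bad])
            sr[bad] = _shear_rates(field, nudged, t + dt)
            still = np.isnan(sr)
            sr[still] = sr_hist[k, idx[still]]
        sr_hist[k + 1, idx] = sr

        # stagnation: trailing-period path length below tolerance
        if k + 1 >= window:
            trailing = pathlen[k + 1, idx] - pathlen[k + 1 - window, idx]
            stag = active[idx] & (trailing < stagnation_tol)
            for p in idx[stag]:
                active[p] = False
                termination[p] = TERMINATION_STAGNATION
                end_step[p] = k + 1

    pathlines = []
    for p in range(P):
        n = min(end_step[p], n_max)
        times = release_time + dt * np.arange(n + 1)
        positions = pos_hist[: n + 1, p].copy()
        sr = sr_hist[: n + 1, p].copy()
        if termination[p] == TERMINATION_OUTLET and np.isfinite(exit_time[p]):
            times[n] = exit_time[p]
            positions[n] = exit_point[p]
        srcum = cumulative_shear(times, sr)
        pathlines.append(
            Pathline(times, positions, sr, srcum, str(termination[p]), int(projections[p]))
        )
    return pathlines


def integrate_pathline(
    field: TimePeriodicVelocityField,
    seed: np.ndarray,
    release_time: float,
    dt: float | None = None,
    max_cycles: int = 30,
    stagnation_tol: float | None = None,
) -> Pathline:
    """Single-seed convenience wrapper around :func:`integrate_pathlines`."""
    return integrate_pathlines(
        field, np.atleast_2d(seed), release_time, dt, max_cycles, stagnation_tol
    )[0]


def cumulative_shear(times: np.ndarray, sr: np.ndarray) -> np.ndarray:
    """Left-endpoint Riemann sum of SR dt; SRcum[0] = 0, non-decreasing."""
    times = np.asarray(times, dtype=float)
    sr = np.nan_to_num(np.asarray(sr, dtype=float))
    if len(times) == 0:
        raise ValueError("pathline must have at least one sample")
    out = np.zeros(len(times))
    if len(times) > 1:
        out[1:] = np.cumsum(sr[:-1] * np.diff(times))
    return out


def track_case(
    field: TimePeriodicVelocityField,
    seeds: SeedSet,
    dt: float | None = None,
    max_cycles: int = 30,
    stagnation_tol: float | None = None,
) -> list[Pathline]:
    """Integrate all release cohorts of a seed set."""
    out = []
    for rt in seeds.release_times:
        out.extend(
            integrate_pathlines(field, seeds.points, float(rt), dt, max_cycles, stagnation_tol)
        )
    return out


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _bin_samples(mesh: Mesh, positions: np.ndarray, values: np.ndarray):
    tri = mesh.locate(positions)
    ok = (tri >= 0) & np.isfinite(values)
    sums = np.zeros(len(mesh.elements))
    counts = np.zeros(len(mesh.elements))
    np.add.at(sums, tri[ok], values[ok])
    np.add.at(counts, tri[ok], 1.0)
    return sums, counts


def reconstruct_cumulative_field(
    pathlines: list[Pathline], mesh: Mesh, release_times: np.ndarray | None = None
) -> CumulativeShearField:
    """Sample-weighted per-element mean of SRcum over all pathlines."""
    if not pathlines:
        raise ValueError("need at least one pathline")
    pos = np.concatenate([p.positions for p in pathlines])
    val = np.concatenate([p.srcum for p in pathlines])
    finite = np.all(np.isfinite(pos), axis=1)
    sums, counts = _bin_samples(mesh, pos[finite], val[finite])
    mean = np.full(len(mesh.elements), np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    if release_times is None:
        release_times = np.unique([p.times[0] for p in pathlines])
    return CumulativeShearField(mean, counts, np.asarray(release_times))


def residence_time_field(pathlines: list[Pathline], mesh: Mesh) -> np.ndarray:
    """Per-element mean residence time (s); NaN where no pathline visited.

    Each pathline contributes its total time spent in an element; the mean is
    taken over the pathlines that visited that element.
    """
    total = np.zeros(len(mesh.elements))
    visits = np.zeros(len(mesh.elements))
    for p in pathlines:
        if len(p.times) < 2:
            continue
        finite = np.all(np.isfinite(p.positions[:-1]), axis=1)
        tri = mesh.locate(p.positions[:-1][finite])
        dts = np.diff(p.times)[finite]
        ok = tri >= 0
        per_elem = np.zeros(len(mesh.elements))
        np.add.at(per_elem, tri[ok], dts[ok])
        nz = per_elem > 0
        total[nz] += per_elem[nz]
        visits[nz] += 1.0
    out = np.full(len(mesh.elements), np.nan)
    nz = visits > 0
    out[nz] = total[nz] / visits[nz]
    return out


def field_l2_change(
    a: CumulativeShearField, b: CumulativeShearField, mesh: Mesh
) -> float:
    """Relative L2 difference of two reconstructions over commonly sampled elements."""
    both = (a.sample_counts > 0) & (b.sample_counts > 0)
    if not both.any():
        raise ValueError("reconstructions share no sampled elements")
    w = mesh.element_measures[both]
    da = a.element_mean[both] - b.element_mean[both]
    ref = np.sqrt(np.sum(w * a.element_mean[both] ** 2))
    return float(np.sqrt(np.sum(w * da**2)) / ref)
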