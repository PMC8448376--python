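"""Analytic, divergence-free, time-periodic velocity fields.

These fields stand in for pre-computed patient CFD: a pulsatile Poiseuille
channel flow (the control vessel with monotone throughflow) and a
stream-function-based aneurysm flow composed of a variable-width throughflow
plus a bulge-localized vortex, which produces recirculation and a stagnation
region.  Both are exactly divergence-free in the continuum because they derive
from a stream function; the stored object is K nodal frames over one period
with periodic linear interpolation in time and barycentric (P1) interpolation
in space, the same representation used for externally supplied fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh

# phase quantization: periodic queries at t and t+T must agree bit-for-bit,
# which raw fmod does not guarantee; 1e-12 of a period is far below any
# physical time scale here
_PHASE_DECIMALS = 12


@dataclass
class TimePeriodicVelocityField:
    """Nodal velocity frames over one cardiac cycle.

    frames : (K, N, 2) cm/s nodal vectors, at frame_times in [0, T)
    """

    mesh: Mesh
    frames: np.ndarray
    period: float
    frame_times: np.ndarray
    stagnation_point: np.ndarray | None = None
    _grad_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.frames.shape[1] != len(self.mesh.nodes):
            raise ValueError("frame node count does not match mesh")
        if np.any(np.diff(self.frame_times) <= 0) or np.any(self.frame_times < 0):
            raise ValueError("frame_times must be ascending in [0, T)")

    # -- time interpolation -------------------------------------------------
    def _frame_weights(self, time: float) -> tuple[int, int, float]:
        K = len(self.frame_times)
        phase = np.round((time / self.period) % 1.0, _PHASE_DECIMALS) % 1.0
        s = phase * K  # frame_times are uniform k*T/K
        a = int(np.floor(s)) % K
        b = (a + 1) % K
        w = s - np.floor(s)
        return a, b, float(w)

    def frame_at(self, time: float) -> np.ndarray:
        """(N, 2) nodal velocity at an arbitrary time (periodic)."""
        a, b, w = self._frame_weights(time)
        if w == 0.0:
            return self.frames[a]
        return (1.0 - w) * self.frames[a] + w * self.frames[b]

    # -- space interpolation ------------------------------------------------
    def sample(self, points: np.ndarray, time: float) -> tuple[np.ndarray, np.ndarray]:
        """Velocity at points; returns (velocities, inside_mask).

        Out-of-domain points get NaN rows and inside=False (a signal for the
        pathline tracker, not an exception).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tri = self.mesh.locate(pts)
        inside = tri >= 0
        out = np.full((len(pts), 2), np.nan)
        if inside.any():
            t_in = tri[inside]
            lam = self.mesh.barycentric(pts[inside], t_in)
            nodal = self.frame_at(time)
            vals = nodal[self.mesh.elements[t_in]]  # (p, 3, 2)
            out[inside] = np.einsum("pi,pij->pj", lam, vals)
        return out, inside

    def element_gradients(self, time: float) -> np.ndarray:
        """(M, 2, 2) per-element velocity gradient G_ab = d u_a / d x_b."""
        a, b, w = self._frame_weights(time)
        key = (a, b, round(w, _PHASE_DECIMALS))
        if key not in self._grad_cache:
            nodal = self.frame_at(time)
            vals = nodal[self.mesh.elements]  # (M, 3, 2)
            g = np.einsum("mia,mib->mab", vals, self.mesh.shape_gradients)
            if len(self._grad_cache) > 4096:
                self._grad_cache.clear()
            self._grad_cache[key] = g
        return self._grad_cache[key]

    def mean_speed(self) -> float:
        """Cycle- and space-averaged speed (nodal mean over all frames)."""
        return float(np.mean(np.linalg.norm(self.frames, axis=2)))


@dataclass
class FlowCase:
    """A mesh + velocity field bundle, the unit the pipeline operates on."""

    mesh: Mesh
    field: TimePeriodicVelocityField
    period: float
    viscosity: float = 0.04  # dyne s / cm^2, standard blood value
    label: str = "external"

    def __post_init__(self):
        if self.period <= 0 or self.viscosity <= 0:
            raise ValueError("period and viscosity must be positive")


def make_pulsatile_poiseuille(
    mesh: Mesh,
    mean_peak_velocity: float,
    pulsatility_amplitude: float,
    period: float,
    n_frames: int,
) -> TimePeriodicVelocityField:
    """Pulsatile Poiseuille flow u_x = U(t) (1 - (y/h)^2) in a channel.

    U(t) = mean_peak_velocity * (1 + a sin(2 pi t / T)); exactly
    divergence-free and no-slip at the walls.
    """
    if mesh.kind != "channel":
        raise ValueError("pulsatile Poiseuille flow requires a channel mesh")
    if not (0 <= pulsatility_amplitude < 1):
        raise ValueError("pulsatility_amplitude must lie in [0, 1)")
    if n_frames < 4:
        raise ValueError("need at least 4 frames per cycle")
    h = mesh.half_height(mesh.nodes[:, 0])
    y = mesh.nodes[:, 1]
    profile = 1.0 - (y / h) ** 2
    times = np.arange(n_frames) * period / n_frames
    U = mean_peak_velocity * (1.0 + pulsatility_amplitude * np.sin(2 * np.pi * times / period))
    frames = np.zeros((n_frames, len(y), 2))
    frames[:, :, 0] = U[:, None] * profile[None, :]
    return TimePeriodicVelocityField(mesh, frames, period, times)


def _recirc_velocity(
    mesh: Mesh,
    points: np.ndarray,
    throughflow_velocity: float,
    vortex_strength: float,
    bulge_span: tuple[float, float],
) -> np.ndarray:
    """Analytic velocity of the stream function psi = C s(eta) + A b(x) w(eta).

    s(eta) = (3 eta - eta^3)/4 carries the Poiseuille-like throughflow
    (u_x = U0 (rp/h)(1-eta^2) at the inlet), w(eta) = (1-eta^2)^2 is the
    vortex envelope and b(x) = sin^2(pi (x-x0)/Lb) localizes it in the bulge.
    Velocity = curl psi, hence exactly divergence-free; psi is constant on
    each wall so the wall-normal velocity vanishes.
    """
    rp = mesh.proximal_radius
    x0, x1 = bulge_span
    Lb = x1 - x0
    x, y = points[:, 0], points[:, 1]
    h = mesh.half_height(x)
    # dh/dx of the cosine bulge profile: h = rp + dr (1 - cos 2 pi s)/2
    s_par = np.clip((x - x0) / Lb, 0.0, 1.0)
    dh = np.zeros_like(x)
    inside_b = (x > x0) & (x < x1)
    dr = mesh.half_height(np.array([x0 + Lb / 2]))[0] - rp
    dh[inside_b] = dr * np.pi * np.sin(2 * np.pi * s_par[inside_b]) / Lb

    eta = np.clip(y / h, -1.0, 1.0)
    C = 4.0 * throughflow_velocity * rp / 3.0
    A = vortex_strength * throughflow_velocity * rp

    sp = 0.75 * (1.0 - eta**2)          # s'(eta)
    w = (1.0 - eta**2) ** 2
    wp = -4.0 * eta * (1.0 - eta**2)    # w'(eta)
    b = np.zeros_like(x)
    bp = np.zeros_like(x)
    b[inside_b] = np.sin(np.pi * s_par[inside_b]) ** 2
    bp[inside_b] = 2.0 * np.pi * np.sin(np.pi * s_par[inside_b]) * np.cos(
        np.pi * s_par[inside_b]
    ) / Lb

    dpsi_deta = C * sp + A * b * wp
    u = dpsi_deta / h
    deta_dx = -eta * dh / h
    v = -(A * bp * w + dpsi_deta * deta_dx)
    return np.column_stack([u, v])


def make_recirculating_field(
    mesh: Mesh,
    throughflow_velocity: float,
    vortex_strength: float,
    period: float,
    n_frames: int,
    pulsatility_amplitude: float = 0.2,
    vortex_pulsatility: float = 0.8,
    vortex_phase_lag: float = np.pi / 2,
) -> TimePeriodicVelocityField:
    """Throughflow plus a bulge-localized vortex on an aneurysm mesh.

    The throughflow part of the stream function is modulated by
    1 + a sin(2 pi t/T) and the vortex part by
    1 + a_v sin(2 pi t/T + phase); each instantaneous field is exactly
    divergence-free.  A nonzero phase lag (the default) makes the vortex wax
    and wane out of phase with the throughflow, so instantaneous streamlines
    reshape over the cycle and inlet particles are entrained into -- and
    trapped in -- the bulge recirculation, as in aneurysmal flow.  With
    vortex_pulsatility=0 and vortex_phase_lag=0 the modulation is uniform,
    streamline shapes are frozen and (for vortex_strength > 0.25) the vortex
    center at mid-bulge, eta = 1/(4 vortex_strength), is an exact stagnation
    point at all times; that location is reported as ``stagnation_point``
    (for the lagged default it is the cycle-mean vortex center).  The
    stagnation contract -- some interior bulge point with cycle-averaged
    speed < 1% of the throughflow velocity -- is verified numerically on
    construction.
    """
    if mesh.kind != "aneurysm":
        raise ValueError("recirculating field requires an aneurysm mesh")
    if vortex_strength < 0:
        raise ValueError("vortex_strength must be non-negative")
    if n_frames < 4:
        raise ValueError("need at least 4 frames per cycle")
    if mesh.bulge_span is None:
        raise ValueError("mesh has no bulge span metadata")
    span = mesh.bulge_span

    both = _recirc_velocity(mesh, mesh.nodes, throughflow_velocity, vortex_strength, span)
    thru = _recirc_velocity(mesh, mesh.nodes, throughflow_velocity, 0.0, span)
    vort = both - thru  # exactly linear in the vortex strength
    times = np.arange(n_frames) * period / n_frames
    amp_t = 1.0 + pulsatility_amplitude * np.sin(2 * np.pi * times / period)
    amp_v = 1.0 + vortex_pulsatility * np.sin(2 * np.pi * times / period + vortex_phase_lag)
    frames = amp_t[:, None, None] * thru[None, :, :] + amp_v[:, None, None] * vort[None, :, :]

    stag = None
    if vortex_strength > 0.25:
        xm = 0.5 * (span[0] + span[1])
        eta_star = 1.0 / (4.0 * vortex_strength)
        stag = np.array([xm, eta_star * mesh.half_height(np.array([xm]))[0]])

    f = TimePeriodicVelocityField(mesh, frames, period, times, stagnation_point=stag)

    # stagnation contract: sample a grid of interior bulge points, including
    # the quasi-stagnant near-wall band of the bulge (|eta| up to 0.999)
    gx = np.linspace(span[0] + 0.05 * (span[1] - span[0]), span[1] - 0.05 * (span[1] - span[0]), 25)
    geta = np.concatenate([np.linspace(-0.99, 0.99, 41), [-0.999, 0.999]])
    GX, GETA = np.meshgrid(gx, geta)
    pts = np.column_stack([GX.ravel(), (GETA * mesh.half_height(GX)).ravel()])
    speeds = np.zeros(len(pts))
    for t in times:
        vel, inside = f.sample(pts, float(t))
        vel[~inside] = 0.0
        speeds += np.linalg.norm(vel, axis=1) / n_frames
    if speeds.min() >= 0.01 * throughflow_velocity:
        raise ValueError(
            "stagnation contract violated: no interior bulge point with "
            "cycle-averaged speed below 1% of throughflow"
        )
    return f
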