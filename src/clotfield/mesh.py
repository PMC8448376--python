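"""Simplicial meshes for idealized vessel geometries.

Meshes are planar (2D) triangulations of a straight channel (the "normal
vessel" control) or a channel with a smooth, cosine-profile symmetric bulge
(the idealized aneurysm).  The data model keeps node coordinates, triangles,
and tagged boundary facets (inlet / outlet / wall); lengths are in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable

import numpy as np
from matplotlib.tri import Triangulation

INLET = "inlet"
OUTLET = "outlet"
WALL = "wall"


@dataclass
class Mesh:
    """Triangle mesh with tagged boundary facets.

    Attributes
    ----------
    nodes : (N, 2) float array, cm
    elements : (M, 3) int array of node indices
    boundary_facets : (F, 2) int array of node-index pairs on the boundary
    facet_tags : (F,) array of {"inlet", "outlet", "wall"}
    kind : "channel", "aneurysm" or "external"
    half_height : callable h(x) for generated geometries, else None
    proximal_radius : inlet half-height for generated geometries
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_facets: np.ndarray
    facet_tags: np.ndarray
    kind: str = "external"
    half_height: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    proximal_radius: float | None = None
    bulge_span: tuple[float, float] | None = None

    @cached_property
    def element_measures(self) -> np.ndarray:
        """Signed-positive triangle areas, cm^2."""
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    @cached_property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @cached_property
    def triangulation(self) -> Triangulation:
        return Triangulation(self.nodes[:, 0], self.nodes[:, 1], self.elements)

    @cached_property
    def trifinder(self):
        return self.triangulation.get_trifinder()

    @cached_property
    def shape_gradients(self) -> np.ndarray:
        """(M, 3, 2) gradients of the linear shape functions per element."""
        p = self.nodes[self.elements]
        grads = np.empty((len(self.elements), 3, 2))
        # for vertex i, grad = rot90(opposite edge) / (2 A)
        for i in range(3):
            a = p[:, (i + 1) % 3]
            b = p[:, (i + 2) % 3]
            edge = b - a
            grads[:, i, 0] = -edge[:, 1]
            grads[:, i, 1] = edge[:, 0]
        # orient: grad_i . (p_i - a) must be positive (value 1 at vertex i)
        det = np.einsum("mi,mi->m", grads[:, 0], p[:, 0] - p[:, 1])
        grads /= det[:, None, None]
        return grads

    def nodes_on(self, tag: str) -> np.ndarray:
        """Sorted unique node indices lying on facets with the given tag."""
        sel = self.facet_tags == tag
        return np.unique(self.boundary_facets[sel])

    @cached_property
    def domain_diameter(self) -> float:
        lo = self.nodes.min(axis=0)
        hi = self.nodes.max(axis=0)
        return float(np.hypot(*(hi - lo)))

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Containing element per point (-1 outside)."""
        pts = np.atleast_2d(points)
        return np.asarray(self.trifinder(pts[:, 0], pts[:, 1]))

    def barycentric(self, points: np.ndarray, tri: np.ndarray) -> np.ndarray:
        """(P, 3) barycentric coordinates of points in given triangles."""
        pts = np.atleast_2d(points)
        p = self.nodes[self.elements[tri]]
        v0 = p[:, 1] - p[:, 0]
        v1 = p[:, 2] - p[:, 0]
        d = pts - p[:, 0]
        det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
        l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
        return np.column_stack([1.0 - l1 - l2, l1, l2])

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if len(self.nodes) == 0:
            raise ValueError("mesh has no nodes")
        if np.any(self.element_measures <= 0):
            raise ValueError("non-positive element measure")
        inlet = set(map(tuple, np.sort(self.boundary_facets[self.facet_tags == INLET], axis=1)))
        outlet = set(map(tuple, np.sort(self.boundary_facets[self.facet_tags == OUTLET], axis=1)))
        if not inlet or not outlet:
            raise ValueError("inlet and outlet facet sets must be non-empty")
        if inlet & outlet:
            raise ValueError("inlet and outlet facets overlap")
        # tagged facets must partition the mesh boundary
        edges = np.sort(
            np.concatenate(
                [self.elements[:, [0, 1]], self.elements[:, [1, 2]], self.elements[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = set(map(tuple, uniq[counts == 1]))
        tagged = set(map(tuple, np.sort(self.boundary_facets, axis=1)))
        if boundary != tagged:
            raise ValueError("tagged facets do not partition the mesh boundary")
        if len(tagged) != len(self.boundary_facets):
            raise ValueError("duplicate boundary facet tags")


def _structured_channel(
    x: np.ndarray, eta: np.ndarray, h_of_x: Callable[[np.ndarray], np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Mapped structured grid: y = eta * h(x); fixed-diagonal triangulation."""
    nx, ny = len(x), len(eta)
    X, ETA = np.meshgrid(x, eta, indexing="ij")
    Y = ETA * h_of_x(X)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            tris.append([a, b, c])
            tris.append([a, c, d])
    return nodes, np.asarray(tris, dtype=np.int64)


def _tag_boundary(nodes: np.ndarray, nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    def nid(i, j):
        return i * ny + j

    facets, tags = [], []
    for j in range(ny - 1):
        facets.append([nid(0, j), nid(0, j + 1)])
        tags.append(INLET)
        facets.append([nid(nx - 1, j), nid(nx - 1, j + 1)])
        tags.append(OUTLET)
    for i in range(nx - 1):
        facets.append([nid(i, 0), nid(i + 1, 0)])
        tags.append(WALL)
        facets.append([nid(i, ny - 1), nid(i + 1, ny - 1)])
        tags.append(WALL)
    return np.asarray(facets, dtype=np.int64), np.asarray(tags)


def build_channel_mesh(length: float, half_height: float, resolution: float) -> Mesh:
    """Rectangular channel [0, length] x [-h, h], inlet at x=0, outlet at x=length.

    Parameters are in cm; ``resolution`` is the target element size.
    """
    if length <= 0 or half_height <= 0 or resolution <= 0:
        raise ValueError("length, half_height and resolution must be positive")
    if resolution > half_height:
        raise ValueError("mesh too coarse: resolution exceeds half_height")
    nx = max(2, int(round(length / resolution))) + 1
    ny = max(2, int(round(2 * half_height / resolution))) + 1
    x = np.linspace(0.0, length, nx)
    eta = np.linspace(-1.0, 1.0, ny)
    h = float(half_height)

    def h_of_x(xq):
        return np.full_like(np.asarray(xq, dtype=float), h)

    nodes, tris = _structured_channel(x, eta, h_of_x)
    facets, tags = _tag_boundary(nodes, nx, ny)
    mesh = Mesh(nodes, tris, facets, tags, kind="channel", half_height=h_of_x,
                proximal_radius=h)
    mesh.validate()
    return mesh


def build_aneurysm_mesh(
    proximal_radius: float,
    bulge_radius: float,
    proximal_length: float,
    bulge_length: float,
    distal_length: float,
    resolution: float,
) -> Mesh:
    """Channel with a smooth symmetric bulge (cosine profile) in the middle.

    The half-height is h(x) = rp + (rb - rp) * (1 - cos(2 pi s)) / 2 for
    s = (x - Lp)/Lb in [0, 1], and rp elsewhere; C^1 at the bulge ends.
    """
    dims = (proximal_radius, bulge_radius, proximal_length, bulge_length,
            distal_length, resolution)
    if any(d <= 0 for d in dims):
        raise ValueError("all aneurysm dimensions must be positive")
    if bulge_radius <= proximal_radius:
        raise ValueError("not an aneurysm: bulge_radius must exceed proximal_radius")
    rp, rb = float(proximal_radius), float(bulge_radius)
    Lp, Lb, Ld = float(proximal_length), float(bulge_length), float(distal_length)
    L = Lp + Lb + Ld

    def h_of_x(xq):
        xq = np.asarray(xq, dtype=float)
        s = np.clip((xq - Lp) / Lb, 0.0, 1.0)
        return rp + (rb - rp) * 0.5 * (1.0 - np.cos(2.0 * np.pi * s))

    nx = max(2, int(round(L / resolution))) + 1
    ny = max(4, int(round(2 * rb / resolution))) + 1
    x = np.linspace(0.0, L, nx)
    eta = np.linspace(-1.0, 1.0, ny)
    nodes, tris = _structured_channel(x, eta, h_of_x)
    facets, tags = _tag_boundary(nodes, nx, ny)
    mesh = Mesh(nodes, tris, facets, tags, kind="aneurysm", half_height=h_of_x,
                proximal_radius=rp, bulge_span=(Lp, Lp + Lb))
    mesh.validate()
    return mesh


def bulge_mask(mesh: Mesh, factor: float = 1.1) -> np.ndarray:
    """Element mask of the aneurysmal region: local half-height > factor * rp.

    For channel meshes (no bulge) the mask covers the whole domain.
    """
    if mesh.half_height is None or mesh.proximal_radius is None:
        raise ValueError("region mask requires a generated geometry")
    h = mesh.half_height(mesh.element_centroids[:, 0])
    mask = h > factor * mesh.proximal_radius
    if not mask.any():
        return np.ones(len(mesh.elements), dtype=bool)
    return mask
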