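"""Triangulated meshes and finite-element matrices for SPDE random fields.

The latent Gaussian Markov random fields live on the vertices of a Delaunay
triangulation built over (thinned) observation locations plus a buffered
boundary ring.  The mass-lumped matrix ``C`` and stiffness matrix ``G``
assembled here are the ingredients of the Matern (nu = 1) precision built in
:mod:`survgam.gmrf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint


class MeshError(ValueError):
    """Degenerate geometry: collinear points, zero-area triangles, ..."""


class OutOfDomainError(ValueError):
    """Points fall outside the mesh hull."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"{len(self.indices)} point(s) outside the mesh hull "
            f"(first offenders: {self.indices[:10]})"
        )


@dataclass
class Mesh:
    """Delaunay triangulation over thinned points + boundary ring.

    Attributes
    ----------
    points : (n, 2) ndarray
        Vertex coordinates in planar km.
    triangles : (m, 3) ndarray of int
        Vertex index triples.
    cutoff_km : float
        Minimum inter-vertex distance used when thinning.
    n_interior : int
        Number of vertices that came from the input points (the remainder
        are boundary-ring vertices, listed last).
    """

    points: np.ndarray
    triangles: np.ndarray
    cutoff_km: float
    n_interior: int
    _tri: Delaunay | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    @property
    def delaunay(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.points)
        return self._tri

    # -- text serialization -------------------------------------------------
    def to_text(self) -> str:
        lines = [f"# survgam mesh cutoff_km={self.cutoff_km} n_interior={self.n_interior}"]
        lines.append(f"vertices {self.n_vertices}")
        lines += [f"{x:.10g} {y:.10g}" for x, y in self.points]
        lines.append(f"triangles {self.triangles.shape[0]}")
        lines += [f"{a} {b} {c}" for a, b, c in self.triangles]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Mesh":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0]
        cutoff = float(header.split("cutoff_km=")[1].split()[0])
        n_int = int(header.split("n_interior=")[1].split()[0])
        nv = int(lines[1].split()[1])
        pts = np.array([[float(v) for v in ln.split()] for ln in lines[2 : 2 + nv]])
        nt = int(lines[2 + nv].split()[1])
        tris = np.array(
            [[int(v) for v in ln.split()] for ln in lines[3 + nv : 3 + nv + nt]], dtype=int
        )
        return cls(points=pts, triangles=tris, cutoff_km=cutoff, n_interior=n_int)


def thin_points(points: np.ndarray, cutoff_km: float) -> np.ndarray:
    """Greedy cutoff thinning in input order.

    The first-seen point is retained; any later point within ``cutoff_km``
    of a retained point is dropped.  Returns indices of retained points.
    """
    points = np.asarray(points, dtype=float)
    kept: list[int] = []
    kept_xy: list[np.ndarray] = []
    c2 = cutoff_km * cutoff_km
    for i, p in enumerate(points):
        if kept_xy:
            d2 = np.sum((np.asarray(kept_xy) - p) ** 2, axis=1)
            if np.min(d2) < c2:
                continue
        kept.append(i)
        kept_xy.append(p)
    return np.asarray(kept, dtype=int)


def _boundary_ring(points: np.ndarray, buffer_km: float, spacing_km: float) -> np.ndarray:
    """Sample the buffered convex hull boundary at ~``spacing_km`` intervals."""
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    ring = hull.buffer(buffer_km, quad_segs=4).exterior
    n = max(8, int(np.ceil(ring.length / spacing_km)))
    ts = np.linspace(0.0, ring.length, n, endpoint=False)
    pts = np.array([ring.interpolate(t).coords[0] for t in ts])
    # deterministic radial wobble: collinear runs of ring samples would
    # otherwise yield degenerate Delaunay triangles along straight edges
    centroid = pts.mean(axis=0)
    vec = pts - centroid
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    wobble = 0.03 * spacing_km * np.sin(2.0 * np.pi * 3.7 * np.arange(n) / n + 0.5)
    return pts + vec / norms * wobble[:, None]


def thin_and_mesh(points: np.ndarray, cutoff_km: float, hull_buffer_km: float) -> Mesh:
    """Thin points by a minimum distance and triangulate with a buffered hull.

    Parameters
    ----------
    points : (n, 2) array
        Candidate vertex locations (planar km), typically tow locations.
    cutoff_km : float
        Minimum distance between retained vertices (greedy, input order).
    hull_buffer_km : float
        Outward buffer of the convex hull forming the boundary ring; a
        sensible default is the assumed spatial range, which limits
        boundary-effect variance inflation at the data locations.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if cutoff_km <= 0:
        raise ValueError(f"cutoff_km must be > 0, got {cutoff_km}")
    if hull_buffer_km <= 0:
        raise ValueError(f"hull_buffer_km must be > 0, got {hull_buffer_km}")
    if points.shape[0] < 3:
        raise MeshError("need at least 3 points to build a mesh")
    keep = thin_points(points, cutoff_km)
    interior = points[keep]
    # collinearity check on the thinned set
    centered = interior - interior.mean(axis=0)
    if interior.shape[0] < 3 or np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise MeshError("points are (nearly) collinear; cannot triangulate")
    spacing = max(cutoff_km, hull_buffer_km / 2.0)
    ring = _boundary_ring(interior, hull_buffer_km, spacing)
    allpts = np.vstack([interior, ring])
    tri = Delaunay(allpts)
    simplices = np.asarray(tri.simplices, dtype=int)
    # prune exactly-degenerate slivers (zero measure; no FEM contribution)
    p0 = allpts[simplices[:, 0]]
    e1 = allpts[simplices[:, 1]] - p0
    e2 = allpts[simplices[:, 2]] - p0
    areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    keep_tri = areas > 1e-9 * np.median(areas)
    return Mesh(
        points=allpts,
        triangles=simplices[keep_tri],
        cutoff_km=cutoff_km,
        n_interior=interior.shape[0],
        _tri=tri,
    )


@dataclass
class SpdeStructures:
    """P1 finite-element matrices on a mesh.

    ``c`` is the mass-lumped (diagonal) matrix, ``g`` the stiffness matrix;
    both are (n_vertices, n_vertices) and sparse.
    """

    c: sp.csc_matrix
    g: sp.csc_matrix

    @property
    def n(self) -> int:
        return self.c.shape[0]


def fem_matrices(mesh: Mesh) -> SpdeStructures:
    """Assemble mass-lumped C and stiffness G from P1 elements.

    For a triangle with vertices v0, v1, v2 and area A the element mass A/3
    is lumped onto each vertex; the element stiffness is the standard
    gradient inner-product matrix of linear hat functions.
    """
    pts = mesh.points
    n = mesh.n_vertices
    cdiag = np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for t_idx, (i, j, k) in enumerate(mesh.triangles):
        p0, p1, p2 = pts[i], pts[j], pts[k]
        e1 = p1 - p0
        e2 = p2 - p0
        det = e1[0] * e2[1] - e1[1] * e2[0]
        area = 0.5 * abs(det)
        if area <= 1e-12:
            raise MeshError(f"triangle {t_idx} (vertices {i},{j},{k}) has zero area")
        idx = (i, j, k)
        for v in idx:
            cdiag[v] += area / 3.0
        # gradients of hat functions: grad_m = rot(opposite edge) / (2A signed)
        edges = {i: p2 - p1, j: p0 - p2, k: p1 - p0}
        grads = {v: np.array([-edges[v][1], edges[v][0]]) / det for v in idx}
        for a in idx:
            for b in idx:
                rows.append(a)
                cols.append(b)
                vals.append(area * float(grads[a] @ grads[b]))
    c = sp.diags(cdiag).tocsc()
    g = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return SpdeStructures(c=c, g=g)


def projection_matrix(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Row-stochastic barycentric weights evaluating vertex fields at points.

    Each row has (up to) 3 non-zeros summing to 1.  Raises
    :class:`OutOfDomainError` listing points outside the mesh hull.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.delaunay
    simplex = tri.find_simplex(points)
    bad = np.nonzero(simplex < 0)[0]
    if bad.size:
        raise OutOfDomainError(bad)
    trans = tri.transform[simplex]
    bary2 = np.einsum("nij,nj->ni", trans[:, :2, :], points - trans[:, 2, :])
    bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
    verts = tri.simplices[simplex]
    npts = points.shape[0]
    rows = np.repeat(np.arange(npts), 3)
    a = sp.coo_matrix(
        (bary.ravel(), (rows, verts.ravel())), shape=(npts, mesh.n_vertices)
    )
    a = a.tocsr()
    # clip tiny negative weights from floating point at simplex edges
    a.data = np.clip(a.data, 0.0, 1.0)
    norm = np.asarray(a.sum(axis=1)).ravel()
    a = sp.diags(1.0 / norm) @ a
    return a.tocsr()
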