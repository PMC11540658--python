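"""Ball-pivoting surface reconstruction over an unorganized point cloud.

A virtual ball of fixed radius rests on three points (its circumscribing
sphere of that radius contains no other point); that triple seeds a
triangle.  The ball then pivots around each front edge — rotating about
the edge away from the triangle it came from — and the first point it
touches extends the mesh.  Edges where no pivot succeeds become boundary
edges; pivoting is repeated for each radius in ascending order so larger
balls bridge gaps the small ones left, and untriangulated regions are
re-seeded.  Output triangles use input points as vertices (no new
geometry is invented) and are wound consistently with the supplied
per-vertex normals.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

__all__ = ["estimate_normals", "ball_pivot"]

_EPS = 1e-12


def estimate_normals(points: np.ndarray, k: int = 16) -> np.ndarray:
    """PCA normals oriented consistently by propagation along an MST.

    Each normal is the least-variance direction of the point's k
    neighborhood; orientation is then made consistent by flipping along a
    breadth-first walk of the minimum spanning tree of the neighborhood
    graph (open surfaces have no global inside, so only mutual
    consistency matters)."""
    n = points.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    nbrs = points[idx]                       # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered)
    _, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]                 # least-variance direction

    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    graph = csr_matrix((np.maximum(dist[:, 1:].ravel(), _EPS), (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)
    mst = minimum_spanning_tree(graph).tocoo()

    adjacency: dict[int, list[int]] = {}
    for a, b in zip(mst.row, mst.col):
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))

    seen = np.zeros(n, dtype=bool)
    for root in range(n):  # one BFS per connected component
        if seen[root]:
            continue
        seen[root] = True
        queue = deque([root])
        while queue:
            cur = queue.popleft()
            for nxt in adjacency.get(cur, ()):
                if not seen[nxt]:
                    if normals[nxt] @ normals[cur] < 0:
                        normals[nxt] = -normals[nxt]
                    seen[nxt] = True
                    queue.append(nxt)
    return normals


def _cross3(a, b):
    """Cross product for (..., 3) arrays without numpy's axis plumbing."""
    return np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]], axis=-1)


def _ball_centers_batch(p0, p1, p2, n0, n1, n2_normals, radius):
    """Centers of radius-balls resting on (p0, p1, x) for a batch of x.

    Returns (m, 3) centers with NaN rows where the triple is degenerate
    or its circumradius exceeds the ball radius.  The center lies on the
    outer side — the side the vertex normals point toward."""
    p2 = np.atleast_2d(p2)
    ab = p1 - p0                              # (3,)
    ac = p2 - p0                              # (m, 3)
    cr = _cross3(ab[None, :], ac)             # (m, 3)
    n2 = np.einsum("ij,ij->i", cr, cr)
    ab2 = ab @ ab
    ac2 = np.einsum("ij,ij->i", ac, ac)
    valid = n2 > _EPS * np.maximum(ab2 * ac2, _EPS)
    n2_safe = np.where(valid, n2, 1.0)
    circ = p0 + (_cross3(cr, ab[None, :]) * ac2[:, None]
                 + _cross3(ac, cr) * ab2) / (2.0 * n2_safe[:, None])
    rc2 = np.einsum("ij,ij->i", circ - p0, circ - p0)
    h2 = radius * radius - rc2
    valid &= h2 > 0
    tri_n = cr / np.sqrt(n2_safe)[:, None]
    hint = np.atleast_2d(n0 + n1 + n2_normals)  # (m, 3)
    flip = np.einsum("ij,ij->i", tri_n, hint) < 0
    tri_n[flip] = -tri_n[flip]
    centers = circ + np.sqrt(np.maximum(h2, 0.0))[:, None] * tri_n
    centers[~valid] = np.nan
    return centers


class _Mesher:
    def __init__(self, points, normals, radii, scale):
        self.points = points
        self.normals = normals
        self.radii = radii
        self.tree = cKDTree(points)
        self.triangles: list[tuple[int, int, int]] = []
        self.tri_set: set[frozenset] = set()
        self.edge_status: dict[frozenset, str] = {}
        self.edge_opposite: dict[frozenset, int] = {}
        self.front: deque = deque()
        self.used = np.zeros(points.shape[0], dtype=bool)
        self.empty_radius_factor = 1.0 - 1e-9
        self.scale = scale

    # -- predicates ------------------------------------------------------

    def _ball_empty(self, center, radius, exclude) -> bool:
        inside = self.tree.query_ball_point(
            center, radius * self.empty_radius_factor - 1e-9 * self.scale)
        return all(p in exclude for p in inside)

    def _oriented(self, i, j, k):
        """Return the triple wound so its face normal follows the vertex normals."""
        tri_n = _cross3(self.points[j] - self.points[i], self.points[k] - self.points[i])
        if tri_n @ (self.normals[i] + self.normals[j] + self.normals[k]) < 0:
            return (i, k, j)
        return (i, j, k)

    # -- mesh bookkeeping ------------------------------------------------

    def _add_triangle(self, tri):
        key = frozenset(tri)
        if key in self.tri_set:
            return False
        self.tri_set.add(key)
        self.triangles.append(tri)
        self.used[list(tri)] = True
        a, b, c = tri
        for e0, e1, opp in ((a, b, c), (b, c, a), (c, a, b)):
            ekey = frozenset((e0, e1))
            status = self.edge_status.get(ekey)
            if status in ("front", "boundary"):
                self.edge_status[ekey] = "inner"  # glued to an existing patch
            elif status == "inner":
                pass  # non-manifold join; keep the first two triangles
            else:
                self.edge_status[ekey] = "front"
                self.edge_opposite[ekey] = opp
                self.front.append((e0, e1, opp))
        return True

    # -- seeding ---------------------------------------------------------

    def _try_seed(self, i, radius) -> bool:
        """Try to rest the ball on point ``i`` and two of its neighbors."""
        pts = self.points
        nbrs = self.tree.query_ball_point(pts[i], 2.0 * radius)
        nbrs = [p for p in nbrs if p != i]
        if len(nbrs) < 2:
            return False
        nbrs.sort(key=lambda p: (pts[p] - pts[i]) @ (pts[p] - pts[i]))
        nbrs = nbrs[:24]  # nearest few suffice; keeps seeding cheap
        for x in range(len(nbrs)):
            j = nbrs[x]
            third = np.array(nbrs[x + 1:], dtype=np.intp)
            if third.size == 0:
                continue
            centers = _ball_centers_batch(
                pts[i], pts[j], pts[third],
                self.normals[i], self.normals[j], self.normals[third], radius)
            for k, center in zip(third, centers):
                k = int(k)
                if np.isnan(center[0]) or frozenset((i, j, k)) in self.tri_set:
                    continue
                if self._ball_empty(center, radius, {i, j, k}):
                    self._add_triangle(self._oriented(i, j, k))
                    return True
        return False

    # -- pivoting --------------------------------------------------------

    def _pivot(self, e0, e1, opp, radius):
        """Roll the ball around directed front edge (e0, e1); return hit point."""
        pts = self.points
        p0, p1, po = pts[e0], pts[e1], pts[opp]
        c_old = _ball_centers_batch(
            p0, p1, po, self.normals[e0], self.normals[e1],
            self.normals[opp], radius)[0]
        if np.isnan(c_old[0]):
            return None
        m = 0.5 * (p0 + p1)
        e_axis = p1 - p0
        e_len = np.sqrt(e_axis @ e_axis)
        if e_len < _EPS:
            return None
        e_axis = e_axis / e_len

        u0 = c_old - m                         # perpendicular to the edge
        u0n = np.sqrt(u0 @ u0)
        if u0n < _EPS:
            return None
        u0 = u0 / u0n
        # in-plane direction from the edge toward the old opposite vertex
        w = po - m
        w = w - (w @ e_axis) * e_axis
        wn = np.sqrt(w @ w)
        if wn < _EPS:
            return None
        w = w / wn
        tangent = _cross3(e_axis, u0)
        if tangent @ w > 0:  # rolling must move the center away from the triangle
            tangent = -tangent
        ez = _cross3(u0, tangent)  # rotation axis, positive sense toward tangent

        cand = [x for x in self.tree.query_ball_point(m, 2.0 * radius)
                if x not in (e0, e1, opp)
                and frozenset((e0, e1, x)) not in self.tri_set
                and self.edge_status.get(frozenset((e0, x))) != "inner"
                and self.edge_status.get(frozenset((e1, x))) != "inner"]
        if not cand:
            return None
        cand = np.array(cand, dtype=np.intp)
        centers = _ball_centers_batch(
            p0, p1, pts[cand], self.normals[e0], self.normals[e1],
            self.normals[cand], radius)
        ok = ~np.isnan(centers[:, 0])
        cand, centers = cand[ok], centers[ok]
        if cand.size == 0:
            return None
        v = centers - m
        v = v - (v @ e_axis)[:, None] * e_axis
        vn = np.sqrt(np.einsum("ij,ij->i", v, v))
        ok = vn > _EPS
        cand, centers, v, vn = cand[ok], centers[ok], v[ok], vn[ok]
        if cand.size == 0:
            return None
        v = v / vn[:, None]
        theta = np.arctan2(_cross3(u0[None, :], v) @ ez, v @ u0)
        theta = np.where(theta < 1e-9, theta + 2.0 * np.pi, theta)
        for pos in np.argsort(theta):
            if self._ball_empty(centers[pos], radius, {e0, e1, int(cand[pos])}):
                return int(cand[pos])
        return None

    # -- driver ----------------------------------------------------------

    def _process_front(self, radius):
        while self.front:
            e0, e1, opp = self.front.popleft()
            key = frozenset((e0, e1))
            if self.edge_status.get(key) != "front":
                continue  # stale entry: edge already glued
            hit = self._pivot(e0, e1, opp, radius)
            if hit is None:
                self.edge_status[key] = "boundary"
                continue
            # the new triangle shares the edge with opposite winding
            self.edge_status[key] = "inner"
            self._add_triangle((e1, e0, hit))

    def run(self):
        for radius in self.radii:
            # boundary edges get another chance with the larger ball
            for key, status in list(self.edge_status.items()):
                if status == "boundary":
                    self.edge_status[key] = "front"
                    e0, e1 = tuple(key)
                    self.front.append((e0, e1, self.edge_opposite[key]))
            self._process_front(radius)
            # each point anchors at most one seed attempt per radius
            for i in range(self.points.shape[0]):
                if not self.used[i] and self._try_seed(i, radius):
                    self._process_front(radius)
        return self.triangles


def ball_pivot(points: np.ndarray, normals: np.ndarray, radii) -> np.ndarray:
    """Run ball pivoting for each radius in ascending order.

    Returns an (M, 3) integer face array indexing ``points``."""
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be positive and strictly ascending")
    scale = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0))) or 1.0
    mesher = _Mesher(points, normals, radii, scale)
    triangles = mesher.run()
    if not triangles:
        return np.empty((0, 3), dtype=np.intp)
    return np.asarray(triangles, dtype=np.intp)
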