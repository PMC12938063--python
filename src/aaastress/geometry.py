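"""Contour stacks, hydraulic diameters, and lofted triangular surface meshes.

Per-slice outer-wall contours (pixel coordinates plus CTA-specific pixel
size and slice spacing) are converted into a physically scaled open-tube
triangular surface mesh suitable for membrane stress analysis.  Vertices are
stored in centimetres; the proximal ring is the lowest slice index by
convention.

The hydraulic diameter of a cross-section is D_h = 4A/P (area over
perimeter), which equals the geometric diameter for a circle and is the
per-slice size measure used to locate the maximal aneurysm dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .nurbs import SliceContour, resample_closed

MM_PER_CM = 10.0


@dataclass(frozen=True)
class ContourStack:
    """Per-slice closed contours ordered proximal -> distal."""

    contours: list[SliceContour]
    slice_spacing: float  # mm
    pixel_size: float  # mm per pixel

    def __post_init__(self) -> None:
        if len(self.contours) < 1:
            raise ValueError("contour stack is empty")
        if self.slice_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("spacing and pixel size must be positive")

    def __len__(self) -> int:
        return len(self.contours)


@dataclass
class SurfaceMesh:
    """Open-tube triangular surface mesh in physical units (cm).

    ``proximal_ring`` / ``distal_ring`` hold the vertex indices of the two
    boundary loops (empty for closed meshes such as spheres)."""

    vertices: np.ndarray  # (V, 3) cm
    triangles: np.ndarray  # (F, 3) int
    proximal_ring: np.ndarray = field(default_factory=lambda: np.array([], int))
    distal_ring: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.proximal_ring = np.asarray(self.proximal_ring, dtype=np.int64)
        self.distal_ring = np.asarray(self.distal_ring, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def boundary_vertices(self) -> np.ndarray:
        return np.concatenate([self.proximal_ring, self.distal_ring])

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices,
                               faces=self.triangles, process=False)

    def boundary_loop_count(self) -> int:
        """Number of open boundary loops (edges used by exactly one face)."""
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary_edges = uniq[counts == 1]
        if len(boundary_edges) == 0:
            return 0
        import networkx as nx

        g = nx.Graph(boundary_edges.tolist())
        return sum(1 for _ in nx.connected_components(g))


# ---------------------------------------------------------------------------
# Cross-sectional measures
# ---------------------------------------------------------------------------

def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon (implicit closing edge), px^2."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    loop = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(loop, axis=0), axis=1).sum())


def hydraulic_diameter(contour: SliceContour) -> float:
    """Hydraulic diameter 4A/P of a closed contour, in cm."""
    area = polygon_area(contour.points)
    perim = polygon_perimeter(contour.points)
    if perim <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    return 4.0 * area / perim * contour.pixel_size / MM_PER_CM


def max_hydraulic_diameter(stack: ContourStack) -> tuple[float, int]:
    """(maximum hydraulic diameter in cm, slice index); ties -> lowest index."""
    if len(stack) == 0:
        raise ValueError("empty contour stack")
    values = np.array([hydraulic_diameter(c) for c in stack.contours])
    idx = int(np.argmax(values))  # argmax returns the first maximum
    return float(values[idx]), idx


# ---------------------------------------------------------------------------
# Lofting
# ---------------------------------------------------------------------------

def _ensure_ccw(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return points if signed > 0 else points[::-1].copy()


def _best_shift(prev_ring: np.ndarray, ring: np.ndarray) -> int:
    """Cyclic shift of ``ring`` minimizing sum of squared distances to
    ``prev_ring`` (start-point alignment; minimizes strip twist)."""
    m = len(ring)
    best, best_cost = 0, np.inf
    for s in range(m):
        cost = np.sum((np.roll(ring, -s, axis=0) - prev_ring) ** 2)
        if cost < best_cost:
            best, best_cost = s, cost
    return best


def loft_mesh(stack: ContourStack, points_per_ring: int = 48) -> SurfaceMesh:
    """Loft a stack of closed contours into an open-tube surface mesh.

    Each contour is resampled to ``points_per_ring`` arc-length-equally
    spaced points with counter-clockwise winding; consecutive rings are
    aligned by the least-squares cyclic shift and joined by an
    alternate-diagonal triangle strip (2 * points_per_ring triangles per
    band).  Vertex coordinates are physical:
    (x_px * pixel_size, y_px * pixel_size, slice * slice_spacing) in cm.
    """
    if len(stack) < 2:
        raise ValueError("lofting needs at least 2 slices")
    m = points_per_ring
    rings = []
    for contour in stack.contours:
        ring = _ensure_ccw(resample_closed(contour.points, m))
        if rings:
            ring = np.roll(ring, -_best_shift(rings[-1], ring), axis=0)
        rings.append(ring)

    n_slices = len(rings)
    vertices = np.empty((n_slices * m, 3))
    for k, ring in enumerate(rings):
        vertices[k * m:(k + 1) * m, 0] = ring[:, 0] * stack.pixel_size
        vertices[k * m:(k + 1) * m, 1] = ring[:, 1] * stack.pixel_size
        vertices[k * m:(k + 1) * m, 2] = k * stack.slice_spacing
    vertices /= MM_PER_CM

    tris = []
    for k in range(n_slices - 1):
        a = k * m + np.arange(m)
        b = (k + 1) * m + np.arange(m)
        a1 = k * m + (np.arange(m) + 1) % m
        b1 = (k + 1) * m + (np.arange(m) + 1) % m
        # alternate-diagonal strip: two triangles per quad
        tris.append(np.column_stack([a, a1, b]))
        tris.append(np.column_stack([a1, b1, b]))
    triangles = np.vstack(tris)

    mesh = SurfaceMesh(
        vertices=vertices,
        triangles=triangles,
        proximal_ring=np.arange(m),
        distal_ring=np.arange((n_slices - 1) * m, n_slices * m),
    )
    return orient_outward(mesh)


def orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    """Flip all triangles if needed so normals point outward.

    The open tube is capped with boundary-loop fans and the signed volume of
    the closed copy is tested; positive volume == outward normals."""
    verts = mesh.vertices
    faces = [mesh.triangles]
    cap_verts = []
    next_idx = len(verts)
    for ring in (mesh.proximal_ring, mesh.distal_ring):
        if len(ring) == 0:
            continue
        loop = _order_loop(mesh, ring)
        center = verts[loop].mean(axis=0)
        cap_verts.append(center)
        c = next_idx
        next_idx += 1
        fan = np.column_stack([
            loop, np.roll(loop, -1), np.full(len(loop), c)
        ])
        faces.append(fan)
    all_verts = np.vstack([verts] + [np.atleast_2d(v) for v in cap_verts]) \
        if cap_verts else verts
    capped = trimesh.Trimesh(vertices=all_verts, faces=np.vstack(faces),
                             process=False)
    if capped.volume < 0:
        return SurfaceMesh(
            vertices=mesh.vertices,
            triangles=mesh.triangles[:, ::-1].copy(),
            proximal_ring=mesh.proximal_ring,
            distal_ring=mesh.distal_ring,
        )
    return mesh


def _order_loop(mesh: SurfaceMesh, ring: np.ndarray) -> np.ndarray:
    """Order boundary ring vertices into a cycle along boundary edges."""
    ring_set = set(int(v) for v in ring)
    edges = np.sort(
        mesh.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = [e for e in uniq[counts == 1]
                if int(e[0]) in ring_set and int(e[1]) in ring_set]
    adj: dict[int, list[int]] = {}
    for e0, e1 in boundary:
        adj.setdefault(int(e0), []).append(int(e1))
        adj.setdefault(int(e1), []).append(int(e0))
    start = int(ring[0])
    loop = [start]
    prev = None
    while True:
        nxt = [v for v in adj[loop[-1]] if v != prev]
        if not nxt:
            break
        prev = loop[-1]
        if nxt[0] == start:
            break
        loop.append(nxt[0])
    return np.array(loop, dtype=np.int64)


# ---------------------------------------------------------------------------
# Element geometry
# ---------------------------------------------------------------------------

class DegenerateElementError(ValueError):
    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"degenerate triangles at indices {self.indices}")


def element_geometry(mesh: SurfaceMesh, min_area: float = 1e-10):
    """Per-triangle area (cm^2), outward unit normal, and centroid (cm).

    Raises :class:`DegenerateElementError` listing any triangle whose area
    falls below ``min_area``.
    """
    v = mesh.vertices
    t = mesh.triangles
    e1 = v[t[:, 1]] - v[t[:, 0]]
    e2 = v[t[:, 2]] - v[t[:, 0]]
    cross = np.cross(e1, e2)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    bad = np.nonzero(areas <= min_area)[0]
    if len(bad):
        raise DegenerateElementError(bad)
    normals = cross / (2.0 * areas)[:, None]
    centroids = v[t].mean(axis=1)
    return areas, normals, centroids
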