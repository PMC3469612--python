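"""Topologically spherical cortical meshes and their geometry.

Source spaces live on per-hemisphere triangle meshes that exist in two
registrations at once: a folded, pial-like shape (mm) on which dipoles and
their outward normals are defined, and a unit-sphere shape with identical
topology on which spherical harmonics, splines and great-arc distances are
defined.  This module builds icospheres, synthetic folded "pseudo-cortex"
fixtures, graph-ring source patches, and the head-center estimate used by
the surface-bias metric.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "CorticalSurface",
    "SourcePatch",
    "SourceSpace",
    "icosphere",
    "k_ring_patch",
    "great_arc_distance",
    "effective_radius",
    "sphere_to_folded_mm",
    "make_pseudo_cortex",
    "head_center",
]

_MAX_ICOSPHERE_LEVEL = 8


@dataclass
class TriMesh:
    """Closed orientable triangle mesh. ``vertices`` in mm, ``faces`` 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces index invalid vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (n_edges, 2) sorted-index array."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def area(self) -> float:
        """Total surface area from summed triangle areas."""
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def vertex_adjacency(self) -> list[np.ndarray]:
        """Per-vertex arrays of neighbouring vertex indices."""
        e = self.edges()
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in e:
            nbr[i].append(j)
            nbr[j].append(i)
        return [np.array(sorted(n), dtype=np.int64) for n in nbr]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (requires outward face winding)."""
        p = self.vertices[self.faces]
        fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms


@dataclass
class CorticalSurface:
    """One hemisphere's source surface: folded (mm) + unit-sphere registrations.

    ``folded`` and ``sphere`` share the same face list; ``normals`` are outward
    unit vectors of the folded geometry at each vertex.
    """

    hemisphere: str
    folded: TriMesh
    sphere: TriMesh
    normals: np.ndarray

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if not np.array_equal(self.folded.faces, self.sphere.faces):
            raise ValueError("folded and sphere meshes must share the same face list")
        r = np.linalg.norm(self.sphere.vertices, axis=1)
        if not np.allclose(r, 1.0, atol=1e-9):
            raise ValueError("sphere vertices must have unit norm (tol 1e-9)")
        self.normals = np.asarray(self.normals, dtype=float)
        if self.normals.shape != self.folded.vertices.shape:
            raise ValueError("one normal per vertex required")
        n = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(n, 1.0, atol=1e-8):
            raise ValueError("normals must be unit vectors")

    @property
    def n_vertices(self) -> int:
        return self.folded.n_vertices


@dataclass
class SourcePatch:
    """Connected set of dipoles around a centre vertex, normal-constrained."""

    hemisphere: str
    center_vertex: int
    vertices: np.ndarray
    amplitudes: np.ndarray
    orientation_mode: str = "normal-constrained"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.center_vertex not in self.vertices:
            raise ValueError("center_vertex must belong to the patch")
        if len(self.amplitudes) != len(self.vertices):
            raise ValueError("one amplitude per patch vertex required")

    @property
    def size(self) -> int:
        return len(self.vertices)


@dataclass
class SourceSpace:
    """Ordered collection of hemispheres; dipoles are stacked left-to-right.

    Global dipole index = hemisphere offset + local vertex index, which is the
    column convention of every gain matrix and basis transform in the package.
    """

    surfaces: list[CorticalSurface] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.surfaces:
            raise ValueError("at least one hemisphere required")

    @property
    def n_sources(self) -> int:
        return sum(s.n_vertices for s in self.surfaces)

    @property
    def offsets(self) -> list[int]:
        out, acc = [], 0
        for s in self.surfaces:
            out.append(acc)
            acc += s.n_vertices
        return out

    def hemisphere_index(self, hemisphere: str) -> int:
        for i, s in enumerate(self.surfaces):
            if s.hemisphere == hemisphere:
                return i
        raise KeyError(f"no such hemisphere: {hemisphere!r}")

    def hemisphere_slice(self, hemisphere: str) -> slice:
        i = self.hemisphere_index(hemisphere)
        off = self.offsets[i]
        return slice(off, off + self.surfaces[i].n_vertices)

    def surface(self, hemisphere: str) -> CorticalSurface:
        return self.surfaces[self.hemisphere_index(hemisphere)]

    def positions_folded(self) -> np.ndarray:
        return np.concatenate([s.folded.vertices for s in self.surfaces])

    def positions_sphere(self) -> np.ndarray:
        return np.concatenate([s.sphere.vertices for s in self.surfaces])

    def normals(self) -> np.ndarray:
        return np.concatenate([s.normals for s in self.surfaces])

    def global_index(self, hemisphere: str, local: np.ndarray | int):
        return self.offsets[self.hemisphere_index(hemisphere)] + local


# ----------------------------------------------------------------------------
# icosphere generation

# icosahedron with vertices on the unit sphere
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def icosphere(level: int) -> TriMesh:
    """Unit icosphere by midpoint subdivision: 10*4^level + 2 vertices.

    Vertex ordering is deterministic for a fixed level (midpoints appended in
    lexicographic-edge order per subdivision pass), so meshes are
    bit-reproducible across runs.
    """
    level = int(level)
    if level < 0 or level > _MAX_ICOSPHERE_LEVEL:
        raise ValueError(f"level must be in [0, {_MAX_ICOSPHERE_LEVEL}]")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    return TriMesh(verts, faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges.sort(axis=1)
    uniq = np.unique(edges, axis=0)  # lexicographic edge keys
    midpoint_index = {(int(i), int(j)): len(verts) + k for k, (i, j) in enumerate(uniq)}
    mids = verts[uniq[:, 0]] + verts[uniq[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_verts = np.concatenate([verts, mids])

    def mid(i, j):
        return midpoint_index[(min(i, j), max(i, j))]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return new_verts, np.array(new_faces, dtype=np.int64)


# ----------------------------------------------------------------------------
# patches and distances


def k_ring_patch(surface: CorticalSurface, center: int, k: int,
                 amplitudes: np.ndarray | None = None) -> SourcePatch:
    """Breadth-first vertex neighbourhood up to graph distance ``k``.

    On a regular interior vertex of an icosphere, k=3 collects the centre plus
    its first three coordination rings: 1 + 6 + 12 + 18 = 37 dipoles.
    """
    mesh = surface.sphere
    if not (0 <= center < mesh.n_vertices):
        raise ValueError(f"invalid center vertex {center}")
    if k < 0:
        raise ValueError("k must be >= 0")
    adjacency = mesh.vertex_adjacency()
    dist = {int(center): 0}
    queue = deque([int(center)])
    order = [int(center)]
    while queue:
        v = queue.popleft()
        if dist[v] == k:
            continue
        for w in adjacency[v]:
            w = int(w)
            if w not in dist:
                dist[w] = dist[v] + 1
                order.append(w)
                queue.append(w)
    vertices = np.array(order, dtype=np.int64)
    if amplitudes is None:
        amplitudes = np.ones(len(vertices))
    return SourcePatch(surface.hemisphere, int(center), vertices, amplitudes)


def great_arc_distance(surface: CorticalSurface, i, j) -> np.ndarray | float:
    """Great-arc angle (radians) between vertices on the hemisphere's sphere map.

    Accepts scalars or index arrays (broadcast pairwise elementwise).
    """
    pos = surface.sphere.vertices
    pi, pj = pos[np.asarray(i)], pos[np.asarray(j)]
    dot = np.clip(np.sum(pi * pj, axis=-1), -1.0, 1.0)
    arc = np.arccos(dot)
    return float(arc) if arc.ndim == 0 else arc


def arc_between_points(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-arc angle between unit vectors ``a`` and broadcastable ``b``."""
    dot = np.clip(np.sum(np.asarray(a) * np.asarray(b), axis=-1), -1.0, 1.0)
    return np.arccos(dot)


def effective_radius(surface: CorticalSurface) -> float:
    """Radius of the sphere with the folded surface's total area: sqrt(A/4pi)."""
    return float(np.sqrt(surface.folded.area() / (4.0 * np.pi)))


def sphere_to_folded_mm(surface: CorticalSurface, arc) -> np.ndarray | float:
    """Convert a great-arc angle on the sphere map to a folded-cortex distance.

    Global scaling by the effective radius sqrt(A_folded/4pi); exact for
    spherical geometries, a deterministic area-preserving proxy otherwise.
    """
    arc = np.asarray(arc, dtype=float)
    if np.any(arc < -1e-12) or np.any(arc > np.pi + 1e-12):
        raise ValueError("arc must lie in [0, pi]")
    out = arc * effective_radius(surface)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------------
# synthetic folded cortex


def make_pseudo_cortex(level: int, fold_amplitude: float = 4.0, fold_frequency: int = 4,
                       hemisphere: str = "left", seed: int = 0, radius: float = 58.0,
                       midline_offset: float = 14.0) -> CorticalSurface:
    """Synthetic folded hemisphere: an icosphere with sinusoidal radial folds.

    The folded shape is the sphere scaled to ``radius`` mm and perturbed by a
    band-limited radial field (random low-order harmonics around degree
    ``fold_frequency``), creating gyral ridges and sulcal valleys whose inward
    walls face each other, as on a real cortex.  Hemispheres are offset left
    (-x) / right (+x) of the midline.  Deterministic under ``seed``.
    """
    if fold_amplitude < 0:
        raise ValueError("fold_amplitude must be >= 0")
    sphere = icosphere(level)
    u = sphere.vertices
    field_vals = np.zeros(len(u))
    if fold_amplitude > 0:
        rng = np.random.default_rng(seed if hemisphere == "left" else seed + 1)
        # band-limited radial perturbation: random plane-wave-like harmonics
        for _ in range(max(3, int(fold_frequency))):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            freq = rng.uniform(0.6, 1.4) * fold_frequency
            phase = rng.uniform(0, 2 * np.pi)
            field_vals += np.cos(freq * np.pi * (u @ direction) + phase)
        field_vals *= fold_amplitude / max(np.abs(field_vals).max(), 1e-12)
    r = radius + field_vals
    folded_vertices = u * r[:, None]
    sign = -1.0 if hemisphere == "left" else 1.0
    folded_vertices[:, 0] += sign * midline_offset
    folded = TriMesh(folded_vertices, sphere.faces)
    normals = folded.vertex_normals()
    return CorticalSurface(hemisphere, folded, sphere, normals)


def make_two_hemisphere_space(level: int, fold_amplitude: float = 4.0,
                              fold_frequency: int = 4, seed: int = 0,
                              radius: float = 58.0, midline_offset: float = 14.0) -> SourceSpace:
    """Left+right pseudo-cortex pair sharing one seed (convenience fixture)."""
    return SourceSpace([
        make_pseudo_cortex(level, fold_amplitude, fold_frequency, "left", seed, radius, midline_offset),
        make_pseudo_cortex(level, fold_amplitude, fold_frequency, "right", seed, radius, midline_offset),
    ])


# ----------------------------------------------------------------------------
# head center


def head_center(sensor_positions: np.ndarray) -> np.ndarray:
    """Centre of the algebraic least-squares axis-aligned ellipsoid fit.

    Fits A x^2 + B y^2 + C z^2 + D x + E y + F z = 1 to the sensor cloud and
    returns (-D/2A, -E/2B, -F/2C).  Needs >= 9 sensors in a genuinely 3-D,
    non-degenerate configuration.
    """
    p = np.asarray(sensor_positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 9:
        raise ValueError("need >= 9 sensor positions of shape (n, 3)")
    design = np.column_stack([p**2, p])
    coeffs, *_ = np.linalg.lstsq(design, np.ones(len(p)), rcond=None)
    quad = coeffs[:3]
    if np.any(np.abs(quad) < 1e-14) or np.any(quad <= 0):
        raise ValueError("degenerate sensor configuration: ellipsoid fit failed")
    return -coeffs[3:] / (2.0 * quad)
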