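"""Surface morphometrics of folded cortical shapes.

Quantifies a triangulated closed surface by discrete curvature (angle-defect
Gaussian curvature, cotangent-Laplacian mean curvature on Voronoi-mixed
areas), Koenderink's shape index

    s = (2/pi) arctan((k1 + k2) / (k1 - k2)),   s in [-1, 1],

the gyrification index GI = area(surface) / area(convex hull), sulcal depth
(distance to the convex-hull boundary), and a fold count from connected
components of deep concave (sulcal) vertices.  Sign convention: outward
normals, convex domes have positive curvature and s = +1; sulcal pits and
valleys carry negative s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

from .geometry import TetMesh

__all__ = [
    "SurfaceGeometry",
    "extract_surface",
    "principal_curvatures",
    "shape_index",
    "gyrification_index",
    "sulcal_depth",
    "count_folds",
    "angle_defect_total",
]


@dataclass
class SurfaceGeometry:
    """Closed oriented triangulated surface with lazily computed curvature."""

    vertices: np.ndarray
    triangles: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.triangles[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
        )
        n_e = len(np.unique(edges, axis=0))
        return self.n_vertices - n_e + len(self.triangles)

    def area(self) -> float:
        p = self.vertices[self.triangles]
        return float(
            0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1).sum()
        )

    def enclosed_volume(self) -> float:
        p = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0)

    def vertex_normals(self) -> np.ndarray:
        if "vnormals" not in self._cache:
            p = self.vertices[self.triangles]
            fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.triangles[:, k], fn)
            vn /= np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)
            self._cache["vnormals"] = vn
        return self._cache["vnormals"]

    @property
    def kappa1(self) -> np.ndarray:
        return principal_curvatures(self)[0]

    @property
    def kappa2(self) -> np.ndarray:
        return principal_curvatures(self)[1]

    @property
    def mean_curvature(self) -> np.ndarray:
        k1, k2 = principal_curvatures(self)
        return 0.5 * (k1 + k2)

    @property
    def gaussian_curvature(self) -> np.ndarray:
        k1, k2 = principal_curvatures(self)
        return k1 * k2


def extract_surface(state_or_positions, mesh: TetMesh) -> SurfaceGeometry:
    """Boundary triangulation carrying the current nodal positions.

    Vertices are reindexed to the boundary nodes; orientation is outward
    (positive enclosed volume).
    """
    positions = getattr(state_or_positions, "positions", state_or_positions)
    positions = np.asarray(positions)
    surf_nodes = np.unique(mesh.boundary_tris)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[surf_nodes] = np.arange(len(surf_nodes))
    tris = remap[mesh.boundary_tris]
    edges = np.sort(tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise ValueError("boundary surface is non-manifold")
    surf = SurfaceGeometry(positions[surf_nodes], tris)
    if surf.enclosed_volume() < 0:
        surf = SurfaceGeometry(surf.vertices, tris[:, [0, 2, 1]])
    return surf


# ---------------------------------------------------------------------------
# Discrete curvature
# ---------------------------------------------------------------------------


def _mixed_areas_and_angles(surface: SurfaceGeometry):
    """Meyer mixed Voronoi areas, interior angles, cotangent weights."""
    V, F = surface.vertices, surface.triangles
    p = V[F]
    area2 = np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    tri_area = 0.5 * area2
    angles = np.empty((len(F), 3))
    cots = np.empty((len(F), 3))
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.einsum("ij,ij->i", a, b)
        sinang = np.linalg.norm(np.cross(a, b), axis=1)
        angles[:, k] = np.arctan2(sinang, cosang)
        cots[:, k] = cosang / np.maximum(sinang, 1e-300)
    # mixed area: Voronoi for non-obtuse triangles, else T/2 at the obtuse
    # corner and T/4 at the others
    lsq = np.empty((len(F), 3))
    for k in range(3):
        e = p[:, (k + 2) % 3] - p[:, (k + 1) % 3]  # edge opposite corner k
        lsq[:, k] = np.einsum("ij,ij->i", e, e)
    obtuse = angles > np.pi / 2
    any_obtuse = obtuse.any(axis=1)
    areas = np.zeros(len(V))
    vor = np.zeros((len(F), 3))
    for k in range(3):
        # Voronoi area at corner k: (1/8)(l_j^2 cot(angle_j) + l_i^2 cot(angle_i))
        j = (k + 1) % 3
        m = (k + 2) % 3
        vor[:, k] = 0.125 * (lsq[:, m] * cots[:, m] + lsq[:, j] * cots[:, j])
    contrib = np.where(
        any_obtuse[:, None],
        np.where(obtuse, tri_area[:, None] / 2.0, tri_area[:, None] / 4.0),
        vor,
    )
    for k in range(3):
        np.add.at(areas, F[:, k], contrib[:, k])
    return areas, angles, cots, tri_area


def _cotan_laplacian(surface: SurfaceGeometry, cots: np.ndarray) -> sparse.csr_matrix:
    V, F = surface.vertices, surface.triangles
    n = len(V)
    rows, cols, vals = [], [], []
    for k in range(3):
        i = F[:, (k + 1) % 3]
        j = F[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def principal_curvatures(surface: SurfaceGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex principal curvatures kappa1 >= kappa2.

    Gaussian curvature from angle defects over mixed areas; mean curvature
    from the cotangent Laplace-Beltrami mean-curvature normal, signed against
    the outward vertex normal (convex regions positive).  Vertices adjacent to
    degenerate triangles (area < 1e-12) are flagged in ``surface._cache
    ['degenerate_vertices']`` rather than raising.
    """
    if "kappa" in surface._cache:
        return surface._cache["kappa"]
    areas, angles, cots, tri_area = _mixed_areas_and_angles(surface)
    V, F = surface.vertices, surface.triangles
    degen = tri_area < 1e-12
    flagged = np.unique(F[degen]) if degen.any() else np.zeros(0, dtype=np.int64)
    surface._cache["degenerate_vertices"] = flagged

    defect = np.full(len(V), 2.0 * np.pi)
    for k in range(3):
        np.add.at(defect, F[:, k], -angles[:, k])
    K_G = defect / np.maximum(areas, 1e-300)

    L = _cotan_laplacian(surface, cots)
    Hn = np.asarray(L @ V) / (2.0 * np.maximum(areas, 1e-300))[:, None]
    # L x of a sphere with outward normals points outward: sign from normals
    n_out = surface.vertex_normals()
    H = np.einsum("ij,ij->i", Hn, n_out)
    disc = np.sqrt(np.maximum(H**2 - K_G, 0.0))
    k1 = H + disc
    k2 = H - disc
    surface._cache["kappa"] = (k1, k2)
    return k1, k2


def angle_defect_total(surface: SurfaceGeometry) -> float:
    """Sum of angle defects; equals 2 pi Euler characteristic (Gauss-Bonnet)."""
    _, angles, _, _ = _mixed_areas_and_angles(surface)
    defect = np.full(surface.n_vertices, 2.0 * np.pi)
    for k in range(3):
        np.add.at(defect, surface.triangles[:, k], -angles[:, k])
    return float(defect.sum())


def shape_index(kappa1: np.ndarray, kappa2: np.ndarray, umbilic_tol: float = 1e-8) -> np.ndarray:
    """Koenderink shape index s = (2/pi) arctan((k1+k2)/(k1-k2)) in [-1, 1].

    Umbilic points (k1 ~ k2) map to sign(H): +1 on convex domes, -1 in pits;
    flat umbilics (both curvatures ~ 0) map to 0.
    """
    k1 = np.asarray(kappa1, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    scale = np.maximum(np.abs(k1), np.abs(k2))
    umbilic = np.abs(k1 - k2) < umbilic_tol * np.maximum(scale, 1.0)
    flat = umbilic & (scale < umbilic_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (2.0 / np.pi) * np.arctan2(k1 + k2, k1 - k2)
    s = np.where(umbilic, np.sign(k1 + k2), s)
    s = np.where(flat, 0.0, s)
    return s


# ---------------------------------------------------------------------------
# Folding summaries
# ---------------------------------------------------------------------------


def _hull(surface: SurfaceGeometry) -> ConvexHull:
    if "hull" not in surface._cache:
        surface._cache["hull"] = ConvexHull(surface.vertices)
    return surface._cache["hull"]


def gyrification_index(surface: SurfaceGeometry) -> float:
    """GI = surface area / convex-hull area; 1 for convex bodies, >1 folded."""
    return surface.area() / _hull(surface).area


def sulcal_depth(surface: SurfaceGeometry) -> np.ndarray:
    """Per-vertex distance to the convex-hull boundary (0 on the hull).

    For points inside a convex body the distance to the boundary equals the
    smallest distance to a face plane, so the hull's facet planes suffice.
    """
    eq = _hull(surface).equations  # n . x + b <= 0 inside
    d = -(surface.vertices @ eq[:, :3].T + eq[:, 3][None, :])
    return np.maximum(d.min(axis=1), 0.0)


def _component_count(surface, member, min_vertices):
    labels = -np.ones(surface.n_vertices, dtype=np.int64)
    idx = np.nonzero(member)[0]
    if len(idx) == 0:
        return 0, labels
    remap = -np.ones(surface.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    edges = np.concatenate(
        [surface.triangles[:, [0, 1]], surface.triangles[:, [1, 2]], surface.triangles[:, [2, 0]]]
    )
    keep = member[edges[:, 0]] & member[edges[:, 1]]
    e = remap[edges[keep]]
    adj = sparse.csr_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(idx), len(idx))
    )
    n_comp, comp = connected_components(adj, directed=False)
    count = 0
    for cidx in range(n_comp):
        members = idx[comp == cidx]
        if len(members) >= min_vertices:
            labels[members] = count
            count += 1
    return count, labels


def count_folds(
    surface: SurfaceGeometry,
    s_threshold: float = -0.25,
    depth_threshold: float | None = None,
    min_vertices: int = 10,
    vertex_mask: np.ndarray | None = None,
    phase: str = "sulci",
) -> tuple[int, np.ndarray]:
    """Count folds as connected components of fold-phase vertices.

    Sulcal vertices have shape index below ``s_threshold`` and depth below the
    hull exceeding ``depth_threshold`` (default 2% of the hull-equivalent
    radius).  Components with fewer than ``min_vertices`` vertices are noise.
    ``vertex_mask`` restricts the count to a region (e.g. a patch).  Returns
    (count, per-vertex component label; -1 = not in the counted phase).

    ``phase`` selects what is counted: ``"sulci"`` (components of deep concave
    vertices), ``"gyri"`` (components of convex crown vertices, shape index
    above ``-s_threshold`` at depth below the threshold), or ``"folds"`` — the
    larger of the two, which stays meaningful for tightly packed folding
    where the sulci percolate into one connected labyrinth and the gyral
    crowns become the isolated phase (and vice versa).  A surface with no
    sulcal vertices at all counts zero folds in every mode.
    """
    if phase not in ("sulci", "gyri", "folds"):
        raise ValueError("phase must be 'sulci', 'gyri' or 'folds'")
    k1, k2 = principal_curvatures(surface)
    s = shape_index(k1, k2)
    depth = sulcal_depth(surface)
    if depth_threshold is None:
        r_equiv = (3.0 * _hull(surface).volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        depth_threshold = 0.02 * r_equiv
    sulcal = (s < s_threshold) & (depth > depth_threshold)
    gyral = (s > -s_threshold) & (depth < depth_threshold)
    if vertex_mask is not None:
        mask = np.asarray(vertex_mask, dtype=bool)
        sulcal &= mask
        gyral &= mask
    n_sulci, sulcal_labels = _component_count(surface, sulcal, min_vertices)
    if phase == "sulci":
        return n_sulci, sulcal_labels
    if n_sulci == 0:  # unfolded surface: one big convex crown is not a fold
        return 0, -np.ones(surface.n_vertices, dtype=np.int64)
    n_gyri, gyral_labels = _component_count(surface, gyral, min_vertices)
    if phase == "gyri":
        return n_gyri, gyral_labels
    return (n_sulci, sulcal_labels) if n_sulci >= n_gyri else (n_gyri, gyral_labels)
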