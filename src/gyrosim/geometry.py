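"""Synthetic two-layer brain-proxy geometry.

Real cortical-folding studies start from MRI-derived tetrahedral meshes of the
developing brain.  Those data are not redistributable, so this module builds
deterministic stand-ins: smooth ellipsoidal solids of mean radius ``R`` with a
cortical layer of thickness ``T`` (``R/T`` of order 10), optional seeded
invaginations mimicking pre-existing sulci, and a flat bilayer slab for
controlled wavelength experiments.  It also computes the material reference
depth ``y`` of every element and the sigmoidal gray/white indicator

    theta(y) = 1 / (1 + exp(10 (y/T - 1)))

which grades tangential growth from the cortex (theta ~ 1) into the white
matter (theta ~ 0).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.special import expit

__all__ = [
    "TetMesh",
    "CorticalField",
    "GeometrySpec",
    "Invagination",
    "generate_brain_proxy",
    "generate_flat_bilayer",
    "compute_reference_depth",
    "nearest_boundary_info",
    "cortical_indicator",
    "build_cortical_field",
    "apply_thickness_modifier",
    "check_watertight",
]


class MeshingError(ValueError):
    """Raised when a geometry spec cannot be meshed."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with an extracted boundary surface.

    ``nodes`` are reference coordinates (length nondimensionalized by the
    brain size R).  ``tets`` are positively oriented 4-tuples of node indices;
    ``boundary_tris`` are outward-oriented faces belonging to exactly one
    tetrahedron.  ``fixed_nodes`` and ``roller_axes`` carry boundary-condition
    flags set by the generators (slab bottom / lateral faces).
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_tris: np.ndarray
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    # roller_axes[i] = list of axes along which node i is constrained (slab sides)
    roller_axes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_tris = np.ascontiguousarray(self.boundary_tris, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes; positive for a valid mesh."""
        p = self.nodes[self.tets]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        d3 = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def volume(self) -> float:
        return float(self.tet_volumes().sum())

    def surface_mesh(self, positions: np.ndarray | None = None) -> trimesh.Trimesh:
        pos = self.nodes if positions is None else positions
        return trimesh.Trimesh(vertices=pos, faces=self.boundary_tris, process=False)

    def validate(self) -> None:
        vols = self.tet_volumes()
        if len(vols) and vols.min() <= 0.0:
            bad = int(np.argmin(vols))
            raise MeshingError(
                f"tetrahedron {bad} has non-positive volume {vols[bad]:.3e}"
            )
        check_watertight(self)


@dataclass
class CorticalField:
    """Per-element cortical layer description.

    ``depth_y`` is the reference distance from the boundary surface,
    ``thickness_T`` the (possibly spatially varying) cortical thickness,
    ``theta`` the gray-matter indicator in [0, 1], and ``growth_mask`` is True
    where the element is allowed to grow (False = growth suppressed, so the
    element always carries tangential stretch 1).  ``normal`` is the reference
    outward normal of the nearest boundary triangle, used as the element's
    tangential-growth axis.
    """

    depth_y: np.ndarray
    thickness_T: np.ndarray
    theta: np.ndarray
    growth_mask: np.ndarray
    normal: np.ndarray
    nearest_tri: np.ndarray

    def copy(self) -> "CorticalField":
        return CorticalField(
            self.depth_y.copy(),
            self.thickness_T.copy(),
            self.theta.copy(),
            self.growth_mask.copy(),
            self.normal.copy(),
            self.nearest_tri.copy(),
        )


@dataclass(frozen=True)
class Invagination:
    """Smooth radial indentation mimicking a pre-existing sulcus.

    ``direction`` seeds the bump center on the surface, ``angular_radius`` is
    its extent in radians, and ``depth_fraction`` in (0, 1) sets the bump depth
    as a fraction of the mean radius R (developing sulci are of the order of a
    few cortical thicknesses deep, i.e. depth fractions of 0.1-0.3 at R/T ~ 10).
    """

    direction: tuple
    angular_radius: float
    depth_fraction: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if not np.all(np.isfinite(d)) or np.linalg.norm(d) == 0:
            raise MeshingError("invagination direction must be a nonzero 3-vector")
        if not (0.0 < self.angular_radius < np.pi):
            raise MeshingError("invagination angular_radius must be in (0, pi)")
        if not (0.0 < self.depth_fraction < 1.0):
            raise MeshingError("invagination depth_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GeometrySpec:
    """Recipe for a deterministic ellipsoidal brain proxy."""

    semi_axes: tuple = (1.0, 1.0, 1.0)
    cortical_thickness: float = 0.1
    target_edge_length: float = 0.15
    invaginations: tuple = ()
    seed: int = 0
    noise_amplitude: float = 0.01  # seeded symmetry-breaking, units of R

    def __post_init__(self):
        axes = np.asarray(self.semi_axes, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise MeshingError("semi_axes must be three positive scalars")
        if not self.cortical_thickness > 0:
            raise MeshingError("cortical_thickness must be positive")
        if self.cortical_thickness >= axes.min():
            raise MeshingError(
                "cortical_thickness must be smaller than the smallest semi-axis"
            )
        if not self.target_edge_length > 0:
            raise MeshingError("target_edge_length must be positive")
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in axes))
        object.__setattr__(
            self,
            "invaginations",
            tuple(
                inv if isinstance(inv, Invagination) else Invagination(*inv)
                for inv in self.invaginations
            ),
        )

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.semi_axes))

    def to_dict(self) -> dict:
        return {
            "semi_axes": list(self.semi_axes),
            "cortical_thickness": self.cortical_thickness,
            "target_edge_length": self.target_edge_length,
            "invaginations": [
                {
                    "direction": list(map(float, inv.direction)),
                    "angular_radius": inv.angular_radius,
                    "depth_fraction": inv.depth_fraction,
                }
                for inv in self.invaginations
            ],
            "seed": self.seed,
            "noise_amplitude": self.noise_amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeometrySpec":
        invs = tuple(
            Invagination(
                tuple(i["direction"]), i["angular_radius"], i["depth_fraction"]
            )
            for i in d.get("invaginations", [])
        )
        return cls(
            semi_axes=tuple(d.get("semi_axes", (1.0, 1.0, 1.0))),
            cortical_thickness=d.get("cortical_thickness", 0.1),
            target_edge_length=d.get("target_edge_length", 0.15),
            invaginations=invs,
            seed=int(d.get("seed", 0)),
            noise_amplitude=float(d.get("noise_amplitude", 0.01)),
        )


# ---------------------------------------------------------------------------
# Boundary extraction / watertightness
# ---------------------------------------------------------------------------

# Outward-oriented faces of a positively oriented tet (n0, n1, n2, n3).
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]], dtype=np.int64)


def _all_faces(tets: np.ndarray) -> np.ndarray:
    return tets[:, _TET_FACES].reshape(-1, 3)


def extract_boundary(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles (faces used by exactly one tet)."""
    faces = _all_faces(tets)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def check_watertight(mesh: TetMesh) -> None:
    """Every interior face shared by exactly 2 tets; boundary faces by 1."""
    faces = _all_faces(mesh.tets)
    key = np.sort(faces, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    if counts.max(initial=1) > 2:
        raise MeshingError("mesh has a face shared by more than two tetrahedra")
    boundary = uniq[counts == 1]
    stored = np.unique(np.sort(mesh.boundary_tris, axis=1), axis=0)
    if boundary.shape != stored.shape or not np.array_equal(boundary, stored):
        raise MeshingError("stored boundary does not match faces of multiplicity one")
    # closed 2-manifold: every boundary edge appears in exactly two boundary tris
    edges = np.sort(
        mesh.boundary_tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
    )
    _, ecounts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(ecounts == 2):
        raise MeshingError("boundary surface is not a closed 2-manifold")


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


# ---------------------------------------------------------------------------
# Shell-based ball meshing
# ---------------------------------------------------------------------------


def _prism_tets(tri: np.ndarray, outer_off: int, inner_off: int) -> list:
    """Split the prism between two radial copies of a triangle into 3 tets.

    Quad diagonals are chosen through the globally smallest vertex index of
    each quad, which makes the decomposition conforming across neighboring
    prisms (Dompierre-style indexed splitting).
    """
    a, b, c = (int(v) for v in tri)
    # rotate so the smallest template index is first; outer copies always have
    # the smaller global offset, so the global minimum sits on the outer tri
    order = [a, b, c]
    k = int(np.argmin(order))
    v0, v1, v2 = order[k:] + order[:k]
    b0, b1, b2 = v0 + outer_off, v1 + outer_off, v2 + outer_off
    t0, t1, t2 = v0 + inner_off, v1 + inner_off, v2 + inner_off
    # quad (v1, v2) x (outer, inner): diagonal through the smaller of v1, v2
    if v1 < v2:
        return [(b0, b1, b2, t2), (b0, b1, t2, t1), (b0, t1, t2, t0)]
    return [(b0, b1, b2, t1), (b0, t1, b2, t2), (b0, t1, t2, t0)]


def _shell_ball_topology(faces: np.ndarray, n_verts: int, n_shells: int):
    """Tets for concentric copies of a sphere triangulation plus a center fan."""
    tets = []
    for k in range(n_shells - 1):
        outer_off = k * n_verts
        inner_off = (k + 1) * n_verts
        for tri in faces:
            tets.extend(_prism_tets(tri, outer_off, inner_off))
    center = n_shells * n_verts
    inner_off = (n_shells - 1) * n_verts
    for tri in faces:
        tets.append(
            (tri[0] + inner_off, tri[1] + inner_off, tri[2] + inner_off, center)
        )
    return np.asarray(tets, dtype=np.int64)


def _radial_fractions(t_frac: float, edge_frac: float) -> np.ndarray:
    """Shell radii (descending from 1) resolving the cortex near the surface."""
    h0 = min(edge_frac, max(t_frac / 2.0, 0.02))
    radii = [1.0]
    r = 1.0
    # uniform layers through the cortical depth band
    while r > 1.0 - 1.4 * t_frac and r - h0 > 0.3:
        r -= h0
        radii.append(r)
    h = h0
    while True:
        # cap the inward coarsening so the center fan stays small enough for
        # centroid-based region masks to resolve the central no-growth ball
        h = min(h * 1.45, 0.16)
        if r - h < 0.16:
            break
        r -= h
        radii.append(r)
    return np.asarray(radii)


def _angular_field(spec: GeometrySpec, dirs: np.ndarray) -> np.ndarray:
    """Radial perturbation (units of R) per unit direction: invaginations + noise."""
    d = np.zeros(len(dirs))
    for inv in spec.invaginations:
        c = np.asarray(inv.direction, dtype=float)
        c /= np.linalg.norm(c)
        ang = np.arccos(np.clip(dirs @ c, -1.0, 1.0))
        inside = ang < inv.angular_radius
        bump = np.zeros(len(dirs))
        # steep-walled profile: sqrt of the raised cosine keeps the full depth
        # at the center but carries sulcus-like steep walls near the rim
        bump[inside] = inv.depth_fraction * np.sqrt(
            0.5 * (1.0 + np.cos(np.pi * ang[inside] / inv.angular_radius))
        )
        d += bump
    if spec.noise_amplitude > 0:
        d += spec.noise_amplitude * _smooth_noise(dirs, spec.seed)
    return d


def _smooth_noise(dirs: np.ndarray, seed: int) -> np.ndarray:
    """Smooth seeded random field on the sphere with unit RMS (bumpy kernel sum)."""
    rng = np.random.default_rng((int(seed) * 2654435761) % 2**31)
    n_bumps = 48
    centers = rng.normal(size=(n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.normal(size=n_bumps)
    # kernel width ~ 30 degrees gives a smooth low-order field
    f = (amps[None, :] * np.exp((dirs @ centers.T - 1.0) / 0.15)).sum(axis=1)
    f -= f.mean()
    rms = np.sqrt((f**2).mean())
    return f / rms if rms > 0 else f


def generate_brain_proxy(spec: GeometrySpec) -> TetMesh:
    """Deterministic two-layer ellipsoidal proxy mesh.

    The ball is meshed as concentric icosphere shells (radially graded, finer
    near the surface so the cortical band is resolved) joined by prisms split
    into conforming tets, with a center fan.  The surface deviates from the
    smooth ellipsoid only inside declared invaginations plus the seeded
    symmetry-breaking noise field, both attenuated quadratically with depth.
    """
    R = spec.mean_radius
    edge_frac = spec.target_edge_length / R
    # icosphere subdivisions: icosahedron edge for unit circumradius ~ 1.0515
    subdiv = int(np.clip(np.ceil(np.log2(1.0515 / edge_frac)), 1, 6))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    dirs = np.asarray(ico.vertices)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)

    t_frac = spec.cortical_thickness / R
    radii = _radial_fractions(t_frac, edge_frac)
    n_shells = len(radii)

    pert = _angular_field(spec, dirs)  # units of R
    axes = np.asarray(spec.semi_axes)
    # smooth ellipsoid base points per direction, then radial perturbation with
    # quadratic depth attenuation (f^2) so the center is untouched
    nodes = np.empty((n_shells * len(dirs) + 1, 3))
    for k, f in enumerate(radii):
        base = f * dirs * axes[None, :]
        # radial coordinate r' = f - f^2 * pert, i.e. scale factor 1 - f * pert
        nodes[k * len(dirs) : (k + 1) * len(dirs)] = base * (1.0 - f * pert)[:, None]
    nodes[-1] = 0.0

    tets = _shell_ball_topology(faces, len(dirs), n_shells)
    tets = _fix_orientation(nodes, tets)
    mesh = TetMesh(nodes, tets, extract_boundary(tets))
    vols = mesh.tet_volumes()
    if vols.min() <= 0:
        raise MeshingError(
            "surface perturbation inverts elements; reduce invagination "
            "depth_fraction or noise_amplitude"
        )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Flat bilayer slab
# ---------------------------------------------------------------------------

# Kuhn subdivision of a hexahedron (conforming across a structured grid)
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def generate_flat_bilayer(
    width: float,
    length: float,
    depth: float,
    cortical_thickness: float,
    target_edge_length: float,
    jitter: float = 0.0,
    seed: int = 0,
) -> TetMesh:
    """Rectangular slab fixture: x in [0, length], y in [0, width], z in [-depth, 0].

    The top face (z = 0) is the growing surface; the bottom face nodes are
    flagged for fixed-displacement boundary conditions and the four lateral
    faces carry roller flags (zero normal displacement), which keeps the
    tangential growth of the top layer fully constrained laterally.

    ``jitter`` > 0 displaces nodes by a smooth seeded field of that amplitude
    (units of the edge length), tangentially to any boundary face they lie on
    except the top, whose vertical jitter provides the symmetry breaking a
    perfectly regular lattice otherwise lacks (a flat lattice is an exact —
    if unstable — equilibrium of the growth problem).
    """
    for name, v in (
        ("width", width),
        ("length", length),
        ("depth", depth),
        ("cortical_thickness", cortical_thickness),
        ("target_edge_length", target_edge_length),
    ):
        if not v > 0:
            raise MeshingError(f"{name} must be positive, got {v}")
    if cortical_thickness >= depth:
        raise MeshingError("cortical_thickness must be smaller than depth")

    h = target_edge_length
    nx = max(1, round(length / h))
    ny = max(1, round(width / h))
    nz = max(2, round(depth / h))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    zs = np.linspace(-depth, 0.0, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = nid(I, J, K).ravel()
    corners = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners[(di, dj, dk)] = nid(I + di, J + dj, K + dk).ravel()
    steps = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
    tet_list = []
    for perm in _KUHN_PERMS:
        c = np.array([0, 0, 0])
        path = [tuple(c)]
        for ax in perm:
            c = c + steps[ax]
            path.append(tuple(c))
        tet_list.append(np.stack([corners[p] for p in path], axis=1))
    tol = 1e-12 * max(length, width, depth)
    if jitter > 0:
        rng = np.random.default_rng(np.uint32(seed) + np.uint32(7919))
        amp = jitter * h
        # smooth low-frequency displacement field evaluated at the nodes
        n_modes = 24
        kvec = rng.uniform(-2.0, 2.0, size=(n_modes, 3)) * 2 * np.pi / max(length, width, depth)
        phase = rng.uniform(0, 2 * np.pi, size=(n_modes, 3))
        coef = rng.normal(size=(n_modes, 3))
        disp = np.zeros_like(nodes)
        for mdx in range(n_modes):
            s = np.cos(nodes @ kvec[mdx] + phase[mdx, 0])
            disp += coef[mdx] * s[:, None]
        disp *= amp / max(np.abs(disp).max(), 1e-30)
        on_x = (np.abs(nodes[:, 0]) < tol) | (np.abs(nodes[:, 0] - length) < tol)
        on_y = (np.abs(nodes[:, 1]) < tol) | (np.abs(nodes[:, 1] - width) < tol)
        on_bot = np.abs(nodes[:, 2] + depth) < tol
        disp[on_x, 0] = 0.0
        disp[on_y, 1] = 0.0
        disp[on_bot, 2] = 0.0
        nodes = nodes + disp

    tets = np.concatenate(tet_list, axis=0)
    tets = _fix_orientation(nodes, tets)
    mesh = TetMesh(nodes, tets, extract_boundary(tets))

    bottom = np.nonzero(np.abs(nodes[:, 2] + depth) < tol)[0]
    mesh.fixed_nodes = bottom
    rollers: dict = {}
    for ax, lo, hi in ((0, 0.0, length), (1, 0.0, width)):
        side = np.nonzero(
            (np.abs(nodes[:, ax] - lo) < tol) | (np.abs(nodes[:, ax] - hi) < tol)
        )[0]
        for n in side:
            rollers.setdefault(int(n), []).append(ax)
    mesh.roller_axes = {n: tuple(a) for n, a in rollers.items()}
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Reference depth and the cortical indicator
# ---------------------------------------------------------------------------


def _point_triangle_distance(points: np.ndarray, tri_pts: np.ndarray) -> np.ndarray:
    """Distances from each point to each triangle; returns (n_points, n_tris)."""
    a = tri_pts[:, 0]
    ab = tri_pts[:, 1] - a
    ac = tri_pts[:, 2] - a
    d1 = np.einsum("tj,ptj->pt", ab, points[:, None, :] - a[None, :, :])
    d2 = np.einsum("tj,ptj->pt", ac, points[:, None, :] - a[None, :, :])
    aa = np.einsum("tj,tj->t", ab, ab)
    bb = np.einsum("tj,tj->t", ac, ac)
    abdot = np.einsum("tj,tj->t", ab, ac)
    # solve for barycentric coords of the unconstrained projection
    det = aa * bb - abdot**2
    det = np.where(det <= 0, 1e-300, det)
    v = (bb * d1 - abdot * d2) / det
    w = (aa * d2 - abdot * d1) / det
    # clamp to the triangle (project onto edges where outside)
    u = 1.0 - v - w
    inside = (v >= 0) & (w >= 0) & (u >= 0)
    # edge AB: param t = d1/aa
    t_ab = np.clip(d1 / np.where(aa > 0, aa, 1e-300), 0.0, 1.0)
    p_ab = a[None] + t_ab[..., None] * ab[None]
    # edge AC
    t_ac = np.clip(d2 / np.where(bb > 0, bb, 1e-300), 0.0, 1.0)
    p_ac = a[None] + t_ac[..., None] * ac[None]
    # edge BC
    b = tri_pts[:, 1]
    bc = tri_pts[:, 2] - b
    cc = np.einsum("tj,tj->t", bc, bc)
    d3 = np.einsum("tj,ptj->pt", bc, points[:, None, :] - b[None, :, :])
    t_bc = np.clip(d3 / np.where(cc > 0, cc, 1e-300), 0.0, 1.0)
    p_bc = b[None] + t_bc[..., None] * bc[None]

    p_in = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    def dist(p):
        return np.linalg.norm(points[:, None, :] - p, axis=2)

    d_edges = np.minimum(np.minimum(dist(p_ab), dist(p_ac)), dist(p_bc))
    d_in = dist(p_in)
    return np.where(inside, np.minimum(d_in, d_edges), d_edges)


def _pt_tri_pairwise(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Distance from points[i] to tris[i] (aligned arrays)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    aa = np.einsum("ij,ij->i", ab, ab)
    bb = np.einsum("ij,ij->i", ac, ac)
    abdot = np.einsum("ij,ij->i", ab, ac)
    det = np.where(aa * bb - abdot**2 <= 0, 1e-300, aa * bb - abdot**2)
    v = (bb * d1 - abdot * d2) / det
    w = (aa * d2 - abdot * d1) / det
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    t_ab = np.clip(d1 / np.where(aa > 0, aa, 1e-300), 0.0, 1.0)
    t_ac = np.clip(d2 / np.where(bb > 0, bb, 1e-300), 0.0, 1.0)
    bc = c - b
    cc = np.einsum("ij,ij->i", bc, bc)
    d3 = np.einsum("ij,ij->i", bc, points - b)
    t_bc = np.clip(d3 / np.where(cc > 0, cc, 1e-300), 0.0, 1.0)

    def dist(p):
        return np.linalg.norm(points - p, axis=1)

    d_edges = np.minimum(
        np.minimum(dist(a + t_ab[:, None] * ab), dist(a + t_ac[:, None] * ac)),
        dist(b + t_bc[:, None] * bc),
    )
    d_in = dist(a + v[:, None] * ab + w[:, None] * ac)
    return np.where(inside, np.minimum(d_in, d_edges), d_edges)


def _brute_nearest(points: np.ndarray, tri_pts: np.ndarray):
    n_t = len(tri_pts)
    chunk = max(1, int(4e6 / max(n_t, 1)))
    dists = np.empty(len(points))
    idx = np.empty(len(points), dtype=np.int64)
    for s in range(0, len(points), chunk):
        d = _point_triangle_distance(points[s : s + chunk], tri_pts)
        idx[s : s + chunk] = np.argmin(d, axis=1)
        dists[s : s + chunk] = d[np.arange(d.shape[0]), idx[s : s + chunk]]
    return dists, idx


def nearest_boundary_info(
    mesh: TetMesh, points: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, boundary-triangle index) of the nearest boundary point.

    Exact: scans every boundary triangle per point with a cheap
    centroid/circumradius lower bound pruning non-competitive triangles (the
    pure-numpy exhaustive scan in ``_brute_nearest`` serves as an independent
    cross-check in the test suite).
    """
    if points is None:
        points = mesh.centroids()
    return _nearest_to_tris(mesh.nodes, mesh.boundary_tris, points)


def _nearest_to_tris(nodes: np.ndarray, tris: np.ndarray, points: np.ndarray):
    from . import _kernels

    points = np.ascontiguousarray(points, dtype=float)
    tri_pts = np.ascontiguousarray(nodes[tris], dtype=float)
    if len(points) == 0:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    return _kernels.nearest_boundary_brute(points, tri_pts)


def compute_reference_depth(mesh: TetMesh, points: np.ndarray | None = None) -> np.ndarray:
    """Per-element reference depth: distance from centroid to the boundary."""
    return nearest_boundary_info(mesh, points)[0]


def cortical_indicator(depth_y: np.ndarray, thickness_T) -> np.ndarray:
    """theta = 1 / (1 + exp(10 (y/T - 1))), elementwise; T may be an array."""
    T = np.asarray(thickness_T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("thickness_T must be positive")
    y = np.asarray(depth_y, dtype=float)
    return expit(-10.0 * (y / T - 1.0))


def _triangle_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.where(norms > 0, norms, 1.0)


def build_cortical_field(
    mesh: TetMesh, thickness: float, tris: np.ndarray | None = None
) -> CorticalField:
    """Depth, indicator, growth normals and an all-grow mask for a mesh.

    The growth axis of each element is the reference outward normal of its
    nearest boundary triangle, fixed once in the reference configuration.
    ``tris`` restricts the boundary triangles that count as the cortical
    surface (e.g. only the top face of a slab, whose lateral walls are
    artifacts of the fixture, not tissue surface); default is the whole
    boundary.
    """
    if not thickness > 0:
        raise ValueError("thickness must be positive")
    surf_tris = mesh.boundary_tris if tris is None else np.asarray(tris, dtype=np.int64)
    depth, tri_idx = _nearest_to_tris(mesh.nodes, surf_tris, mesh.centroids())
    normals = _triangle_normals(mesh.nodes, surf_tris)[tri_idx]
    T = np.full(mesh.n_tets, float(thickness))
    theta = cortical_indicator(depth, T)
    mask = np.ones(mesh.n_tets, dtype=bool)
    return CorticalField(depth, T, theta, mask, normals, tri_idx)


def apply_thickness_modifier(
    mesh: TetMesh,
    field_: CorticalField,
    factor: float,
    region: tuple | None = None,
    transition_frac: float = 0.5,
) -> CorticalField:
    """Multiply the cortical thickness by ``factor`` globally or in a patch.

    ``region`` is ``None`` (whole domain) or ``(direction, angular_radius)``:
    a geodesic patch of surface directions around ``direction`` as seen from
    the mesh centroid.  Inside the patch the factor applies fully and blends
    back to 1 with a half-cosine over a transition band of width
    ``transition_frac * angular_radius``.  theta is recomputed from the
    modified thickness.
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    out = field_.copy()
    if region is None:
        out.thickness_T = out.thickness_T * factor
    else:
        direction, ang_radius = region
        d = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0 or not ang_radius > 0:
            raise ValueError("region requires a nonzero direction and positive radius")
        d = d / nrm
        center = mesh.nodes.mean(axis=0)
        rel = mesh.centroids() - center
        rel /= np.linalg.norm(rel, axis=1, keepdims=True)
        ang = np.arccos(np.clip(rel @ d, -1.0, 1.0))
        band = transition_frac * ang_radius
        blend = np.zeros(mesh.n_tets)
        blend[ang <= ang_radius] = 1.0
        in_band = (ang > ang_radius) & (ang < ang_radius + band)
        blend[in_band] = 0.5 * (1.0 + np.cos(np.pi * (ang[in_band] - ang_radius) / band))
        if not np.any(blend > 0):
            raise ValueError("thickness modifier region contains no elements")
        out.thickness_T = out.thickness_T * (1.0 + blend * (factor - 1.0))
    out.theta = cortical_indicator(out.depth_y, out.thickness_T)
    return out


def mesh_digest(mesh: TetMesh) -> str:
    """SHA-256 over node coordinates and connectivity (determinism checks)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.tets).tobytes())
    return h.hexdigest()
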