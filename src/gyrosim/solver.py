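"""Quasistatic relaxation of the growing two-layer solid.

The energy is discretized on linear tetrahedra and minimized by damped
explicit dynamics: semi-implicit Euler with mass-proportional damping (and an
optional kinetic-energy reset that accelerates quasistatic settling).  The
volumetric (J-1)^2 term is evaluated on nodal-averaged volume ratios so the
linear tets do not lock; near-inverted elements are handled by a clamped
signed SVD; self-contact of the boundary surface uses penalty vertex-triangle
forces found through a uniform spatial hash.

Time is not physical here: lengths are in units of the brain size R, stresses
in units of mu, the nodal density is 1 and element masses are stiffness-scaled
so one global stable timestep serves the whole (radially graded) mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constitutive import MaterialParams
from .geometry import CorticalField, TetMesh

__all__ = [
    "IntegratorParams",
    "ContactParams",
    "SimState",
    "ExplicitSolver",
    "SolverError",
    "stable_timestep",
    "element_forces",
    "nodal_volume_ratio",
    "handle_inversion",
]


class SolverError(RuntimeError):
    """Non-finite forces or another unrecoverable solver failure."""


@dataclass(frozen=True)
class IntegratorParams:
    """Explicit integrator controls.

    ``dt``: time step (None = derived from the mesh via the stability
    estimate).  ``damping``: mass-proportional coefficient; the quasistatic
    regime wants damping * dt of order 0.1.  ``density``: nodal mass scale.
    ``residual_tol``: force tolerance in units of mu * h^2 per node.
    """

    dt: float | None = None
    damping: float | None = None
    density: float = 1.0
    residual_tol: float = 1e-4
    max_steps: int = 20000
    kinetic_damping: bool = True
    safety: float = 0.3

    def __post_init__(self):
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.damping is not None and not self.damping > 0:
            raise ValueError("damping must be positive in the quasistatic regime")
        if not self.density > 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ContactParams:
    """Penalty self-contact: linear stiffness (force per unit penetration),
    detection cutoff, and the spatial-hash cell size (lengths in R)."""

    penalty_stiffness: float
    detection_cutoff: float
    hash_cell_size: float | None = None

    def __post_init__(self):
        if not self.penalty_stiffness > 0:
            raise ValueError("penalty_stiffness must be positive")
        if not self.detection_cutoff > 0:
            raise ValueError("detection_cutoff must be positive")
        if self.hash_cell_size is not None and not self.hash_cell_size > 0:
            raise ValueError("hash_cell_size must be positive")

    @property
    def cell_size(self) -> float:
        return self.hash_cell_size or 2.0 * self.detection_cutoff


@dataclass
class SimState:
    """Current nodal kinematics plus solver diagnostics."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    g_schedule: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.velocities.copy(),
            self.time,
            self.g_schedule,
            dict(self.diagnostics),
        )


# ---------------------------------------------------------------------------
# Standalone operations (reference implementations; also used by tests)
# ---------------------------------------------------------------------------


def _tet_min_altitudes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    vols = (
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        / 6.0
    )
    faces = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
    areas = np.stack(
        [
            0.5
            * np.linalg.norm(
                np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]]), axis=1
            )
            for f in faces
        ],
        axis=1,
    )
    return 3.0 * np.abs(vols) / areas.max(axis=1)


def stable_timestep(mesh: TetMesh, mat: MaterialParams, density: float = 1.0, safety: float = 0.3) -> float:
    """dt = safety * h_min * sqrt(density / (K + 2 mu)), h_min = min element altitude."""
    h_min = float(_tet_min_altitudes(mesh.nodes, mesh.tets).min())
    return safety * h_min * np.sqrt(density / (mat.K_bulk + 2.0 * mat.mu))


def element_forces(
    X_ref: np.ndarray,
    x_cur: np.ndarray,
    mat: MaterialParams,
    G: np.ndarray | None = None,
    nodal_J: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Forces on the 4 nodes of one tet and its energy (pure-numpy reference).

    With ``nodal_J`` given (4 nodal-averaged volume ratios), the volumetric
    stress uses the mean nodal pressure instead of the element J; energy then
    reports only the isochoric part (the volumetric energy lives on nodes).
    """
    X_ref = np.asarray(X_ref, dtype=float)
    x_cur = np.asarray(x_cur, dtype=float)
    Dm = (X_ref[1:] - X_ref[0]).T
    det = np.linalg.det(Dm)
    if abs(det) < 1e-300:
        raise ValueError("degenerate reference tetrahedron")
    V = det / 6.0
    if V <= 0:
        raise ValueError("reference tetrahedron must be positively oriented")
    Dminv = np.linalg.inv(Dm)
    Ds = (x_cur[1:] - x_cur[0]).T
    F = Ds @ Dminv
    if G is None:
        G = np.eye(3)
    Ginv = np.linalg.inv(G)
    Fe = F @ Ginv
    Je = np.linalg.det(Fe)
    Fe = _kernels.sanitize_gradient(np.ascontiguousarray(Fe))
    Je = np.linalg.det(Fe)
    I1 = float(np.einsum("ij,ij->", Fe, Fe))
    Jm23 = Je ** (-2.0 / 3.0)
    FeinvT = np.linalg.inv(Fe).T
    P_iso = mat.mu * Jm23 * (Fe - (I1 / 3.0) * FeinvT)
    energy = V * 0.5 * mat.mu * (I1 * Jm23 - 3.0)
    if nodal_J is None:
        pbar = mat.K_bulk * (Je - 1.0)
        energy += V * 0.5 * mat.K_bulk * (Je - 1.0) ** 2
    else:
        pbar = mat.K_bulk * float(np.mean(np.asarray(nodal_J) - 1.0))
    P = P_iso + pbar * Je * FeinvT
    H = V * P @ (Dminv @ Ginv).T
    forces = np.empty((4, 3))
    forces[1:] = -H.T
    forces[0] = H.sum(axis=1)
    return forces, float(energy)


def nodal_volume_ratio(mesh: TetMesh, positions: np.ndarray) -> np.ndarray:
    """Reference-volume-weighted average of element J over the tets at each node:
    Jbar(a) = sum_e V_ref J_e / sum_e V_ref."""
    p_ref = mesh.nodes[mesh.tets]
    p_cur = np.asarray(positions)[mesh.tets]
    Dm = np.stack([(p_ref[:, k] - p_ref[:, 0]) for k in (1, 2, 3)], axis=2)
    Ds = np.stack([(p_cur[:, k] - p_cur[:, 0]) for k in (1, 2, 3)], axis=2)
    J = np.linalg.det(Ds) / np.linalg.det(Dm)
    Vref = mesh.tet_volumes()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for k in range(4):
        np.add.at(num, mesh.tets[:, k], Vref * J)
        np.add.at(den, mesh.tets[:, k], Vref)
    if np.any(den == 0):
        raise ValueError("mesh contains an isolated node")
    return num / den


def handle_inversion(F: np.ndarray) -> np.ndarray:
    """Sanitized elastic gradient for (near-)inverted states.

    Signed SVD with det U = det V = 1; singular values below the floor
    (including negative ones) are clamped, so stresses evaluated on the result
    are finite, continuous across det F = 0, and act to restore volume.
    """
    return np.asarray(_kernels.sanitize_gradient(np.ascontiguousarray(F, dtype=float)))


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


class ExplicitSolver:
    """Damped explicit quasistatics on a fixed mesh with scheduled growth.

    The growth magnitude per element is g_eff = 1 + theta (g_schedule - 1)
    (masked elements stay at 1) along the fixed reference surface normal.
    Element masses below the stability requirement for the chosen dt are
    scaled up (selective mass scaling), which is inconsequential for the
    quasistatic equilibria we seek.
    """

    def __init__(
        self,
        mesh: TetMesh,
        field_: CorticalField,
        mat: MaterialParams = MaterialParams(),
        integrator: IntegratorParams = IntegratorParams(),
        contact: ContactParams | None = None,
        use_nodal_pressure: bool = True,
    ):
        self.mesh = mesh
        self.field = field_
        self.mat = mat
        self.contact = contact
        self.use_nodal_pressure = use_nodal_pressure

        p = mesh.nodes[mesh.tets]
        Dm = np.stack([(p[:, k] - p[:, 0]) for k in (1, 2, 3)], axis=2)
        self.Dminv = np.ascontiguousarray(np.linalg.inv(Dm))
        self.Vref = np.ascontiguousarray(mesh.tet_volumes())
        self.node_Vsum = np.zeros(mesh.n_nodes)
        for k in range(4):
            np.add.at(self.node_Vsum, mesh.tets[:, k], self.Vref)
        self.total_Vref = float(self.Vref.sum())

        h = _tet_min_altitudes(mesh.nodes, mesh.tets)
        self.h_elem = h
        self.h_ref = float(np.median(h))
        dt = integrator.dt
        if dt is None:
            dt = integrator.safety * self.h_ref * np.sqrt(
                integrator.density / (mat.K_bulk + 2.0 * mat.mu)
            )
        damping = integrator.damping
        if damping is None:
            damping = 0.1 / dt
        self.integrator = replace(integrator, dt=dt, damping=damping)
        self._build_masses()
        self._build_surface()
        self._build_constraints()
        self.growth_normal = np.ascontiguousarray(field_.normal, dtype=np.float64)
        self.g_eff = np.ones(mesh.n_tets)
        self._contact_ref_pos = None
        self._contact_pairs = None

    # -- setup ------------------------------------------------------------

    def _build_masses(self):
        it = self.integrator
        stiff = self.mat.K_bulk + 2.0 * self.mat.mu
        # selective mass scaling: elements smaller than the stable size for dt
        # get proportionally heavier so the global dt remains stable
        rho_req = stiff * (it.dt / (0.5 * self.h_elem)) ** 2
        rho = np.maximum(it.density, rho_req)
        m = np.zeros(self.mesh.n_nodes)
        for k in range(4):
            np.add.at(m, self.mesh.tets[:, k], 0.25 * rho * self.Vref)
        if self.contact is not None:
            surf = np.unique(self.mesh.boundary_tris)
            m[surf] += 4.0 * self.contact.penalty_stiffness * it.dt**2
        self.masses = m

    def _build_surface(self):
        tris = self.mesh.boundary_tris
        self.surf_verts = np.unique(tris)
        # exclusion: triangles containing the vertex or any 1-ring neighbor
        vert_tris: dict[int, set] = {int(v): set() for v in self.surf_verts}
        for t, tri in enumerate(tris):
            for v in tri:
                vert_tris[int(v)].add(t)
        neighbors: dict[int, set] = {int(v): {int(v)} for v in self.surf_verts}
        for tri in tris:
            for v in tri:
                neighbors[int(v)].update(int(u) for u in tri)
        indptr = [0]
        excl = []
        for v in self.surf_verts:
            tset = set()
            for u in neighbors[int(v)]:
                tset |= vert_tris[u]
            excl.extend(sorted(tset))
            indptr.append(len(excl))
        self.excl_indptr = np.asarray(indptr, dtype=np.int64)
        self.excl_tris = np.asarray(excl, dtype=np.int64)
        self.surf_tris = np.ascontiguousarray(tris, dtype=np.int64)
        edges = self.mesh.nodes[tris[:, [1, 2, 0]]] - self.mesh.nodes[tris]
        self.surface_edge_length = float(np.linalg.norm(edges, axis=2).mean())

    def _build_constraints(self):
        free = np.ones((self.mesh.n_nodes, 3))
        for n in self.mesh.fixed_nodes:
            free[n] = 0.0
        for n, axes in self.mesh.roller_axes.items():
            for ax in axes:
                free[n, ax] = 0.0
        self.dof_mask = free
        self.free_nodes = np.nonzero(free.any(axis=1))[0]

    # -- growth -----------------------------------------------------------

    def set_growth(self, g_schedule: float) -> None:
        g = 1.0 + self.field.theta * (g_schedule - 1.0)
        g[~self.field.growth_mask] = 1.0
        self.g_eff = np.ascontiguousarray(g)
        self._g_schedule = g_schedule

    def grown_target_volume(self) -> float:
        """Reference volume after stress-free growth: sum V_ref det(G)."""
        return float((self.Vref * self.g_eff**2).sum())

    # -- forces -----------------------------------------------------------

    def compute_forces(self, positions: np.ndarray) -> tuple[np.ndarray, dict]:
        f = np.zeros_like(positions)
        Jbar = np.zeros(self.mesh.n_nodes)
        e_iso, e_vol, min_J = _kernels.assemble_forces(
            positions,
            self.mesh.tets,
            self.Dminv,
            self.Vref,
            self.growth_normal,
            self.g_eff,
            self.mat.mu,
            self.mat.K_bulk,
            self.use_nodal_pressure,
            self.node_Vsum,
            f,
            Jbar,
        )
        info = {
            "iso_energy": e_iso,
            "vol_energy": e_vol,
            "min_J": min_J,
            "max_penetration": 0.0,
            "contact_energy": 0.0,
        }
        if self.contact is not None:
            pen, e_c = self._contact(positions, f)
            info["max_penetration"] = pen
            info["contact_energy"] = e_c
        info["energy"] = e_iso + e_vol + info["contact_energy"]
        if not np.all(np.isfinite(f)):
            bad = int(np.argmax(~np.isfinite(f).all(axis=1)))
            raise SolverError(
                f"non-finite forces at node {bad}, position {positions[bad]}, "
                f"min element J {min_J:.3e}"
            )
        return f, info

    def _contact(self, positions: np.ndarray, f: np.ndarray) -> tuple[float, float]:
        """Penalty contact with a cached candidate pair list.

        Candidates are detected within 1.5x the cutoff and remain valid while
        no surface node has moved more than 0.25x the cutoff since detection
        (pair distances then change by at most the 0.5-cutoff margin, so no
        contact can be missed)."""
        cutoff = self.contact.detection_cutoff
        refresh = self._contact_ref_pos is None
        if not refresh:
            moved = np.abs(positions[self.surf_verts] - self._contact_ref_pos).max()
            refresh = moved > 0.25 * cutoff
        if refresh:
            self._contact_pairs = _kernels.find_contact_pairs(
                positions,
                self.surf_verts,
                self.surf_tris,
                self.excl_indptr,
                self.excl_tris,
                1.5 * cutoff,
                self.contact.cell_size,
            )
            self._contact_ref_pos = positions[self.surf_verts].copy()
        return _kernels.pair_contact_forces(
            positions,
            self._contact_pairs[0],
            self._contact_pairs[1],
            self.surf_tris,
            cutoff,
            self.contact.penalty_stiffness,
            f,
        )

    def residual(self, forces: np.ndarray) -> float:
        masked = forces * self.dof_mask
        return float(np.linalg.norm(masked, axis=1).max())

    @property
    def residual_scale(self) -> float:
        """Force scale mu * h^2 used to nondimensionalize the residual tolerance."""
        return self.mat.mu * self.h_ref**2

    # -- time stepping ----------------------------------------------------

    def step(self, state: SimState, forces: np.ndarray | None = None) -> SimState:
        """One damped semi-implicit Euler step:
        v <- (v + dt f / m) (1 - damping dt); x <- x + dt v (fixed DOFs pinned)."""
        it = self.integrator
        if forces is None:
            forces, info = self.compute_forces(state.positions)
        else:
            info = dict(state.diagnostics)
        v = state.velocities + it.dt * forces / self.masses[:, None]
        v *= 1.0 - it.damping * it.dt
        v *= self.dof_mask
        x = state.positions + it.dt * v
        return SimState(x, v, state.time + it.dt, state.g_schedule, info)

    def relax_to_equilibrium(
        self,
        state: SimState,
        residual_tol: float | None = None,
        max_steps: int | None = None,
    ) -> tuple[SimState, dict]:
        """Iterate damped steps until the residual force drops below tolerance.

        Uses kinetic-energy resets (dynamic relaxation) when enabled.  On
        non-convergence returns the best state reached plus a warning flag —
        not an exception.
        """
        it = self.integrator
        tol = (residual_tol if residual_tol is not None else it.residual_tol) * self.residual_scale
        max_steps = max_steps if max_steps is not None else it.max_steps
        st = state.copy()
        best = st
        best_res = np.inf
        ke_prev = 0.0
        steps = 0
        while True:
            f, info = self.compute_forces(st.positions)
            res = self.residual(f)
            st.diagnostics = {**info, "residual": res}
            if res < best_res:
                best_res = res
                best = st
            if res <= tol or steps >= max_steps:
                break
            st = self.step(st, forces=f)
            st.diagnostics = info
            if it.kinetic_damping:
                ke = float((self.masses[:, None] * st.velocities**2).sum())
                if ke < ke_prev:
                    st.velocities[:] = 0.0
                    ke = 0.0
                ke_prev = ke
            steps += 1
        converged = best_res <= tol
        best.diagnostics["residual"] = best_res
        best.diagnostics["converged"] = converged
        return best, {"converged": converged, "steps": steps, "residual": best_res}

    # -- diagnostics -------------------------------------------------------

    def total_energy(self, positions: np.ndarray) -> float:
        _, info = self.compute_forces(positions)
        return info["energy"]

    def current_volume(self, positions: np.ndarray) -> float:
        p = np.asarray(positions)[self.mesh.tets]
        vols = (
            np.einsum(
                "ij,ij->i",
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                p[:, 3] - p[:, 0],
            )
            / 6.0
        )
        return float(vols.sum())

    def energy_breakdown(self, positions: np.ndarray) -> dict:
        """Independent vectorized re-evaluation of the discretized energy
        (numpy path, no numba), for cross-checking the assembled total."""
        p_cur = np.asarray(positions)[self.mesh.tets]
        Ds = np.stack([(p_cur[:, k] - p_cur[:, 0]) for k in (1, 2, 3)], axis=2)
        F = Ds @ self.Dminv
        n = self.growth_normal
        g = self.g_eff
        ig = 1.0 / g
        nnT = np.einsum("ei,ej->eij", n, n)
        Ginv = ig[:, None, None] * (np.eye(3)[None] - nnT) + nnT
        Fe = F @ Ginv
        Je = np.linalg.det(Fe)
        I1g = np.einsum("eij,eij->e", Fe, Fe)
        for e in np.nonzero(Je < 0.5 * _kernels.EPS_J * I1g)[0]:
            Fe[e] = _kernels.sanitize_gradient(np.ascontiguousarray(Fe[e]))
            Je[e] = np.linalg.det(Fe[e])
        I1 = np.einsum("eij,eij->e", Fe, Fe)
        e_iso = float((self.Vref * 0.5 * self.mat.mu * (I1 * Je ** (-2 / 3) - 3.0)).sum())
        if self.use_nodal_pressure:
            num = np.zeros(self.mesh.n_nodes)
            for k in range(4):
                np.add.at(num, self.mesh.tets[:, k], self.Vref * Je)
            Jbar = num / self.node_Vsum
            e_vol = float(
                (0.5 * self.mat.K_bulk * (Jbar - 1.0) ** 2 * 0.25 * self.node_Vsum).sum()
            )
        else:
            e_vol = float((self.Vref * 0.5 * self.mat.K_bulk * (Je - 1.0) ** 2).sum())
        return {"iso_energy": e_iso, "vol_energy": e_vol, "energy": e_iso + e_vol}

    def initial_state(self) -> SimState:
        return SimState(self.mesh.nodes.copy(), np.zeros_like(self.mesh.nodes))
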