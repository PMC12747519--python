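"""Growth scenarios: the normal ferret configuration and malformation presets.

A scenario bundles geometry, material, the developmental growth schedule, and
the perturbation factors that model malformations of cortical development:

* ``normal``        — reference parameters: R/T ~ 10, tangential stretch
                      target g ~ 1.9 (areal cortical expansion g^2).
* ``thin_global``   — cortical thickness reduced to 1/4 everywhere (dense,
                      tightly packed small folds).
* ``thick_global``  — thickness doubled everywhere (far fewer folds).
* ``pmg_local``     — thickness reduced to 1/4 in a localized lateral patch
                      (polymicrogyria-like excess local folding).
* ``microcephaly``  — tangential growth rate reduced to 1/4 (under-folding).
* ``tmem_like``     — growth reduced to 3/4 with thickness times 1.5
                      (shallow sulci, lissencephaly-like).

"Reduction of the growth rate to x of the original" multiplies the excess
stretch (g - 1) by x, so factor 0 means no growth; scaling g itself or the
areal ratio g^2 is available through ``growth_rate_semantics``.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constitutive import MaterialParams
from .geometry import (
    CorticalField,
    GeometrySpec,
    TetMesh,
    apply_thickness_modifier,
    build_cortical_field,
    generate_brain_proxy,
    generate_flat_bilayer,
    _triangle_normals,
)
from .morphometrics import count_folds, extract_surface, gyrification_index
from .solver import ContactParams, ExplicitSolver, IntegratorParams, SimState

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "preset",
    "PRESETS",
    "growth_schedule",
    "no_growth_mask",
    "run_scenario",
    "desk_scenario",
]

PRESETS = ("normal", "thin_global", "thick_global", "pmg_local", "microcephaly", "tmem_like")

# the localized thin patch sits on the lateral equator of the proxy;
# the real perisylvian zone is anatomical and not transferable exactly
_PMG_PATCH_DIRECTION = (1.0, 0.0, 0.0)
_PMG_PATCH_RADIUS = np.deg2rad(30.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully serializable description of one growth simulation."""

    geometry: GeometrySpec = GeometrySpec()
    material: MaterialParams = MaterialParams()
    R_over_T: float = 10.0
    g_target: float = 1.9
    growth_factor: float = 1.0
    thickness_factor: float = 1.0
    thickness_region: tuple | None = None  # None = global, else (direction, radius)
    schedule: str = "continuous"  # or "stepwise"
    stage_fractions: tuple = (0.125, 0.125, 0.25, 0.5)
    no_growth_central_frac: float = 0.3
    no_growth_bottom_frac: float = 0.15
    n_increments: int = 100
    seed: int = 0
    growth_rate_semantics: str = "excess"  # 'excess' (g-1), 'g', or 'g2'
    integrator: IntegratorParams = IntegratorParams()
    contact_stiffness_scale: float = 40.0  # x mu x surface edge
    contact_cutoff_scale: float = 0.4  # x surface edge
    relax_tol: float = 2e-3
    relax_max_steps: int = 400
    final_relax_max_steps: int = 2000
    kind: str = "ellipsoid"  # or "slab"
    slab_dims: tuple = (0.25, 4.0, 1.0)  # width, length, depth
    slab_jitter: float = 0.3

    def __post_init__(self):
        if self.g_target < 1.0:
            raise ValueError("g_target must be >= 1")
        if not (self.growth_factor >= 0 and self.thickness_factor > 0):
            raise ValueError("growth_factor must be >= 0 and thickness_factor > 0")
        if self.schedule not in ("continuous", "stepwise"):
            raise ValueError("schedule must be 'continuous' or 'stepwise'")
        if abs(sum(self.stage_fractions) - 1.0) > 1e-9:
            raise ValueError("stage fractions must sum to 1")
        if self.growth_rate_semantics not in ("excess", "g", "g2"):
            raise ValueError("growth_rate_semantics must be 'excess', 'g' or 'g2'")

    @property
    def cortical_thickness(self) -> float:
        return self.geometry.mean_radius / self.R_over_T

    def to_dict(self) -> dict:
        d = {
            "geometry": self.geometry.to_dict(),
            "material": {"mu": self.material.mu, "K_bulk": self.material.K_bulk},
            "R_over_T": self.R_over_T,
            "g_target": self.g_target,
            "growth_factor": self.growth_factor,
            "thickness_factor": self.thickness_factor,
            "thickness_region": (
                None
                if self.thickness_region is None
                else [list(map(float, self.thickness_region[0])), float(self.thickness_region[1])]
            ),
            "schedule": self.schedule,
            "stage_fractions": list(self.stage_fractions),
            "no_growth_central_frac": self.no_growth_central_frac,
            "no_growth_bottom_frac": self.no_growth_bottom_frac,
            "n_increments": self.n_increments,
            "seed": self.seed,
            "growth_rate_semantics": self.growth_rate_semantics,
            "integrator": {
                "dt": self.integrator.dt,
                "damping": self.integrator.damping,
                "density": self.integrator.density,
                "residual_tol": self.integrator.residual_tol,
                "max_steps": self.integrator.max_steps,
                "kinetic_damping": self.integrator.kinetic_damping,
                "safety": self.integrator.safety,
            },
            "contact_stiffness_scale": self.contact_stiffness_scale,
            "contact_cutoff_scale": self.contact_cutoff_scale,
            "relax_tol": self.relax_tol,
            "relax_max_steps": self.relax_max_steps,
            "final_relax_max_steps": self.final_relax_max_steps,
            "kind": self.kind,
            "slab_dims": list(self.slab_dims),
            "slab_jitter": self.slab_jitter,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        kw = dict(d)
        if "geometry" in kw:
            kw["geometry"] = GeometrySpec.from_dict(kw["geometry"])
        if "material" in kw:
            kw["material"] = MaterialParams(**kw["material"])
        if "integrator" in kw:
            kw["integrator"] = IntegratorParams(**kw["integrator"])
        if kw.get("thickness_region") is not None:
            direction, radius = kw["thickness_region"]
            kw["thickness_region"] = (tuple(direction), float(radius))
        for key in ("stage_fractions", "slab_dims"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def preset(name: str, **overrides) -> ScenarioConfig:
    """Named scenario presets; unknown names raise listing the options."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset '{name}'; available: {', '.join(PRESETS)}")
    base = ScenarioConfig(**overrides)
    if name == "normal":
        return base
    if name == "thin_global":
        return replace(base, thickness_factor=0.25)
    if name == "thick_global":
        return replace(base, thickness_factor=2.0)
    if name == "pmg_local":
        return replace(
            base,
            thickness_factor=0.25,
            thickness_region=(_PMG_PATCH_DIRECTION, _PMG_PATCH_RADIUS),
        )
    if name == "microcephaly":
        return replace(base, growth_factor=0.25)
    return replace(base, growth_factor=0.75, thickness_factor=1.5)  # tmem_like


def growth_schedule(t_frac: float, config: ScenarioConfig) -> float:
    """Scheduled tangential stretch at developmental fraction t in [0, 1].

    Linear ramp in stretch.  Under the default 'excess' semantics the target
    is 1 + growth_factor (g_target - 1); 'g' scales g itself and 'g2' scales
    the areal ratio g^2.
    """
    if not 0.0 <= t_frac <= 1.0:
        raise ValueError("t_frac must lie in [0, 1]")
    g, f = config.g_target, config.growth_factor
    if config.growth_rate_semantics == "excess":
        g_final = 1.0 + f * (g - 1.0)
    elif config.growth_rate_semantics == "g":
        g_final = max(f * g, 1.0)
    else:  # 'g2'
        g_final = max(np.sqrt(f) * g, 1.0)
    return 1.0 + t_frac * (g_final - 1.0)


def no_growth_mask(mesh: TetMesh, config: ScenarioConfig) -> np.ndarray:
    """True where growth is suppressed: within ``no_growth_central_frac * R``
    of the body centroid, or below the bottom plane at
    ``no_growth_bottom_frac`` of the bounding-box height."""
    import warnings

    cent = mesh.centroids()
    body_center = mesh.nodes.mean(axis=0)
    R = config.geometry.mean_radius
    central = np.linalg.norm(cent - body_center, axis=1) < config.no_growth_central_frac * R
    zmin, zmax = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
    bottom = cent[:, 2] < zmin + config.no_growth_bottom_frac * (zmax - zmin)
    mask = central | bottom
    vols = mesh.tet_volumes()
    if mask.all() or (vols[mask].sum() > 0.95 * vols.sum()):
        warnings.warn("no-growth mask covers more than 95% of the domain")
    return mask


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    mesh: TetMesh
    field: CorticalField
    state: SimState
    metrics: list  # list of per-increment dicts
    converged: bool
    warnings: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # (g, positions) if requested

    def surface(self):
        return extract_surface(self.state.positions, self.mesh)

    def metrics_csv(self) -> str:
        if not self.metrics:
            return ""
        buf = io.StringIO()
        fieldnames = list(self.metrics[0].keys())
        for row in self.metrics:  # later rows may add sparse columns
            fieldnames += [k for k in row if k not in fieldnames]
        writer = csv.DictWriter(buf, fieldnames=fieldnames, restval="")
        writer.writeheader()
        for row in self.metrics:
            writer.writerow({k: repr(v) if isinstance(v, float) else v for k, v in row.items()})
        return buf.getvalue()


def _build_domain(config: ScenarioConfig):
    """Mesh + cortical field (thickness modifiers and no-growth mask applied)."""
    T = config.cortical_thickness
    if config.kind == "slab":
        w, l, d = config.slab_dims
        mesh = generate_flat_bilayer(
            w, l, d, T, config.geometry.target_edge_length,
            jitter=config.slab_jitter, seed=config.seed,
        )
        tn = _triangle_normals(mesh.nodes, mesh.boundary_tris)
        top = mesh.boundary_tris[tn[:, 2] > 0.5]
        fld = build_cortical_field(mesh, T, tris=top)
    else:
        # the mesh must radially resolve the thinnest cortex present, so the
        # meshing thickness tracks the (global or local) modifier
        T_mesh = T * min(config.thickness_factor, 1.0)
        geom = replace(
            config.geometry, cortical_thickness=T_mesh, seed=config.seed
        )
        mesh = generate_brain_proxy(geom)
        fld = build_cortical_field(mesh, T)
        fld.growth_mask &= ~no_growth_mask(mesh, config)
    if config.thickness_factor != 1.0:
        fld = apply_thickness_modifier(
            mesh, fld, config.thickness_factor, region=config.thickness_region
        )
    return mesh, fld


def _make_solver(config: ScenarioConfig, mesh: TetMesh, fld: CorticalField) -> ExplicitSolver:
    edge = config.geometry.target_edge_length
    contact = ContactParams(
        penalty_stiffness=config.contact_stiffness_scale * config.material.mu * edge,
        detection_cutoff=config.contact_cutoff_scale * edge,
    )
    solver = ExplicitSolver(mesh, fld, config.material, config.integrator, contact)
    if config.integrator.damping is None:
        # light viscous damping: the kinetic-energy resets do the settling
        object.__setattr__(solver.integrator, "damping", 0.02 / solver.integrator.dt)
    return solver


def run_scenario(
    config: ScenarioConfig,
    out_dir=None,
    progress=None,
    keep_snapshots: bool = False,
    resume_state: SimState | None = None,
) -> ScenarioResult:
    """End-to-end run: build domain, ramp growth incrementally with quasistatic
    relaxation after each increment, and collect per-increment metrics.

    ``continuous`` ramps t 0 -> 1 in ``n_increments`` steps.  ``stepwise``
    splits the ramp at the stage boundaries and rebases the material reference
    onto the relaxed state at each boundary (the original protocol restarts
    from a new imaged brain at every stage; lacking such data the relaxed
    state stands in for it), re-deriving depth, indicator and growth normals
    on the new reference.  ``resume_state`` restarts a continuous run from a
    checkpoint: increments whose scheduled growth was already applied are
    skipped.
    """
    mesh, fld = _build_domain(config)
    solver = _make_solver(config, mesh, fld)
    state = solver.initial_state()
    resume_g = 1.0
    if resume_state is not None:
        if config.schedule != "continuous":
            raise ValueError("resume is only supported for continuous schedules")
        if resume_state.positions.shape != state.positions.shape:
            raise ValueError("checkpoint does not match the configured mesh")
        state = resume_state.copy()
        resume_g = resume_state.g_schedule
    snapshots: list = []
    metrics: list = []
    warnings_list: list = []
    converged_all = True

    if config.schedule == "stepwise":
        bounds = np.cumsum((0.0,) + tuple(config.stage_fractions))
    else:
        bounds = np.array([0.0, 1.0])

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "trajectory").mkdir(parents=True, exist_ok=True)
        (out_dir / "metrics").mkdir(parents=True, exist_ok=True)
        (out_dir / "config-echo.json").write_text(json.dumps(config.to_dict(), indent=2))

    inc_total = 0
    g_base = 1.0  # accumulated growth absorbed into the reference (stepwise)
    for s_idx in range(len(bounds) - 1):
        t0, t1 = bounds[s_idx], bounds[s_idx + 1]
        n_inc = max(1, round(config.n_increments * (t1 - t0)))
        for k in range(1, n_inc + 1):
            t = t0 + (t1 - t0) * k / n_inc
            g_total = growth_schedule(t, config)
            if g_total <= resume_g + 1e-12 and not (k == n_inc and s_idx == len(bounds) - 2):
                continue  # already applied before the checkpoint
            solver.set_growth(g_total / g_base)
            last = k == n_inc and s_idx == len(bounds) - 2
            state, info = solver.relax_to_equilibrium(
                state,
                residual_tol=config.relax_tol,
                max_steps=config.final_relax_max_steps if last else config.relax_max_steps,
            )
            converged_all &= bool(info["converged"])
            state.g_schedule = g_total
            inc_total += 1
            row = {
                "increment": inc_total,
                "t_frac": t,
                "g_schedule": g_total,
                "steps": info["steps"],
                "residual": info["residual"],
                "energy": state.diagnostics.get("energy", np.nan),
                "min_J": state.diagnostics.get("min_J", np.nan),
                "max_penetration": state.diagnostics.get("max_penetration", 0.0),
            }
            if config.kind != "slab":
                surf = extract_surface(state.positions, mesh)
                row["gyrification_index"] = gyrification_index(surf)
                if inc_total % 10 == 0 or last:
                    row["fold_count"] = count_folds(surf)[0]
            metrics.append(row)
            if keep_snapshots:
                snapshots.append((g_total, state.positions.copy()))
            if progress is not None:
                progress(row)
            if out_dir is not None and (inc_total % 10 == 0 or last):
                from .mesh_io import write_mesh

                write_mesh(
                    TetMesh(state.positions, mesh.tets, mesh.boundary_tris),
                    out_dir / "trajectory" / f"inc_{inc_total:04d}.vtu",
                    cell_data={"theta": fld.theta, "g_eff": solver.g_eff},
                )
        if s_idx < len(bounds) - 2:
            # stage boundary: rebase the reference onto the relaxed state
            g_base = growth_schedule(t1, config)
            mesh = TetMesh(
                state.positions.copy(), mesh.tets, mesh.boundary_tris,
                fixed_nodes=mesh.fixed_nodes, roller_axes=mesh.roller_axes,
            )
            fld2 = build_cortical_field(mesh, fld.thickness_T.mean())
            fld2.thickness_T = fld.thickness_T
            fld2.theta = fld.theta
            fld2.growth_mask = fld.growth_mask
            fld = fld2
            solver = _make_solver(config, mesh, fld)
            state = SimState(mesh.nodes.copy(), np.zeros_like(mesh.nodes))

    result = ScenarioResult(config, mesh, fld, state, metrics, converged_all, warnings_list)
    result.snapshots = snapshots
    if out_dir is not None:
        (out_dir / "metrics" / "metrics.csv").write_text(result.metrics_csv())
    return result


def desk_slab(thickness_factor: float = 1.0, seed: int = 0, **overrides) -> ScenarioConfig:
    """Flat-bilayer wavelength experiment at desk scale.

    A quasi-2D slab (0.25 x 4 x 1, laterally roller-constrained) with cortex
    T = 0.25 scaled by ``thickness_factor``; the edge length 0.0625 resolves a
    half-thickness cortex with two elements and its folding wavelength
    (~3.5 T) with several elements.
    """
    # quasi-2D strip, each case meshed at a third of its own cortical
    # thickness (wavelength selection needs both a resolved layer and deep
    # relaxation: under-relaxed runs freeze the perturbation spectrum instead
    # of the mechanically selected wavelength)
    T_eff = 0.25 * thickness_factor
    edge = T_eff / 3.0
    kw = dict(
        geometry=GeometrySpec(
            semi_axes=(1.0, 1.0, 1.0),
            cortical_thickness=0.25,
            target_edge_length=edge,
            seed=seed,
        ),
        kind="slab",
        slab_dims=(2.0 * edge, 4.5, 0.75),
        R_over_T=4.0,
        thickness_factor=thickness_factor,
        n_increments=30,
        relax_max_steps=400,
        final_relax_max_steps=3000,
        seed=seed,
    )
    kw.update(overrides)
    return ScenarioConfig(**kw)


def slab_top_profile(mesh: TetMesh, positions: np.ndarray, n_bins: int = 128):
    """Mean top-surface height vs the reference (material) length coordinate.

    Binning by the reference x keeps the profile gap-free even when the folded
    surface bunches material into the sulci."""
    tn = _triangle_normals(mesh.nodes, mesh.boundary_tris)
    top = np.unique(mesh.boundary_tris[tn[:, 2] > 0.5])
    x = mesh.nodes[top, 0]
    z = positions[top, 2]
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    prof = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            prof[b] = z[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = np.isfinite(prof)
    return centers[ok], prof[ok]


def _profile_minima_spacing(x: np.ndarray, z: np.ndarray) -> tuple[float, int]:
    """Median spacing of prominent profile minima (prominence 0.3 std)."""
    from scipy.signal import find_peaks

    z = z - z.mean()
    kernel = np.array([0.25, 0.5, 0.25])
    zs = np.convolve(np.pad(z, 1, mode="edge"), kernel, mode="valid")
    peaks, _ = find_peaks(-zs, prominence=0.3 * zs.std(), distance=2)
    if len(peaks) == 0:
        return float("inf"), 0
    if len(peaks) == 1:
        return float(x.max() - x.min()), 1
    return float(np.median(np.diff(x[peaks]))), len(peaks)


def slab_onset_wavelength(
    result: ScenarioResult, deflection_factor: float = 0.6
) -> tuple[float, int]:
    """Primary folding wavelength measured at the emergence of folding.

    Deep past onset a strongly overstressed thin layer folds hierarchically
    (deep broad sulci over short cusps), which pollutes any single-wavelength
    summary; the primary instability wavelength — the quantity that scales
    with the cortical thickness — is read off at the first growth increment
    where the top-surface deflection range exceeds ``deflection_factor``
    times the cortical thickness.  Requires a run with ``keep_snapshots``.
    """
    if not result.snapshots:
        raise ValueError("slab_onset_wavelength needs run_scenario(keep_snapshots=True)")
    T_eff = result.config.cortical_thickness * result.config.thickness_factor
    for _, positions in result.snapshots:
        x, z = slab_top_profile(result.mesh, positions)
        if z.max() - z.min() >= deflection_factor * T_eff:
            return _profile_minima_spacing(x, z)
    x, z = slab_top_profile(result.mesh, result.snapshots[-1][1])
    return _profile_minima_spacing(x, z)


def slab_fold_wavelength(mesh: TetMesh, positions: np.ndarray) -> tuple[float, int]:
    """Dominant fold wavelength of a folded slab.

    Sulci are connected intervals of the (smoothed, y-averaged) top profile
    descending below 35% of the deepest trough.  The wavelength is the median
    spacing between adjacent sulcus centers, which ignores any not-yet-folded
    dead zones that would bias a simple length-over-count estimate; with
    fewer than two sulci it falls back to length / count."""
    x, z = slab_top_profile(mesh, positions)
    z = z - z.mean()
    # light smoothing over ~3 bins suppresses mesh-scale noise
    kernel = np.array([0.25, 0.5, 0.25])
    zs = np.convolve(np.pad(z, 1, mode="edge"), kernel, mode="valid")
    threshold = zs.min() * 0.35
    deep = zs < threshold
    starts = list(np.nonzero(deep[1:] & ~deep[:-1])[0] + 1)
    if deep[0]:
        starts = [0] + starts
    ends = list(np.nonzero(~deep[1:] & deep[:-1])[0])
    if deep[-1]:
        ends = ends + [len(deep) - 1]
    centers = np.array([0.5 * (x[a] + x[b]) for a, b in zip(starts, ends)])
    n_sulci = len(centers)
    if n_sulci == 0:
        return float("inf"), 0
    if n_sulci == 1:
        return float(x.max() - x.min()), 1
    return float(np.median(np.diff(centers))), n_sulci


def desk_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Scaled-down study configuration for desk-size trend experiments.

    The reference runs use million-element imaged meshes; at desk scale the
    cortex must stay mesh-resolved, so these configurations use a coarser
    R/T = 4 with an icosphere-shell proxy of ~17k tets and 30 growth
    increments.  Presets' perturbation factors are untouched.
    """
    T = 1.0 / 3.0
    kw = dict(
        geometry=GeometrySpec(
            semi_axes=(1.0, 1.0, 1.0),
            cortical_thickness=T,
            target_edge_length=0.15,
            seed=seed,
            noise_amplitude=0.01,
        ),
        R_over_T=3.0,
        n_increments=20,
        relax_max_steps=300,
        final_relax_max_steps=1500,
        seed=seed,
    )
    kw.update(overrides)
    cfg = preset(name, **kw)
    # the mesh must also resolve the folding wavelength of the thinnest cortex
    # present (~3.5 T); cap the tangential edge at ~0.8 of that thickness
    T_min = cfg.cortical_thickness * min(cfg.thickness_factor, 1.0)
    edge = min(cfg.geometry.target_edge_length, 0.8 * T_min)
    if edge != cfg.geometry.target_edge_length and "geometry" not in overrides:
        cfg = replace(cfg, geometry=replace(cfg.geometry, target_edge_length=edge))
        # fine meshes (quarter-thickness cortex) get a shorter schedule so the
        # whole scenario suite stays desk-sized; the localized-thinning case
        # folds later than global thinning (the patch is embedded in a
        # non-folding matrix) and keeps a longer one
        if "n_increments" not in overrides:
            if cfg.thickness_region is None:
                cfg = replace(
                    cfg, n_increments=8, relax_max_steps=120, final_relax_max_steps=400
                )
            else:
                cfg = replace(
                    cfg, n_increments=14, relax_max_steps=220, final_relax_max_steps=800
                )
    return cfg
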