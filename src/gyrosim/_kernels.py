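"""Numba kernels for the explicit quasistatic solver.

Single-threaded, deterministic inner loops: element force assembly for the
neo-Hookean energy with multiplicative tangential growth, nodal-averaged
volume ratios for the nodal-pressure treatment, SVD-based inversion handling,
and penalty vertex-triangle self-contact with a uniform spatial hash.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# floor on elastic singular values used when an element approaches/passes
# inversion; stresses evaluated on the clamped state stay finite and push the
# element back toward positive volume
EPS_J = 0.05
# elements with det(Fe) below this go through the SVD path
SVD_THRESHOLD = 0.30


@njit(cache=False, fastmath=True)
def _det3(a):
    return (
        a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
        - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
        + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0])
    )


@njit(cache=False, fastmath=True)
def _inv3(a, out):
    d = _det3(a)
    invd = 1.0 / d
    out[0, 0] = (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]) * invd
    out[0, 1] = (a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]) * invd
    out[0, 2] = (a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]) * invd
    out[1, 0] = (a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]) * invd
    out[1, 1] = (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]) * invd
    out[1, 2] = (a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]) * invd
    out[2, 0] = (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]) * invd
    out[2, 1] = (a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]) * invd
    out[2, 2] = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) * invd


@njit(cache=False)
def _signed_svd(F):
    """SVD with det(U) = det(V) = 1; the smallest singular value carries the
    sign of det(F) (rotation-consistent decomposition for inversion handling)."""
    U, s, Vt = np.linalg.svd(F)
    s = s.copy()
    U = U.copy()
    Vt = Vt.copy()
    if np.linalg.det(U) < 0.0:
        U[:, 2] = -U[:, 2]
        s[2] = -s[2]
    if np.linalg.det(Vt) < 0.0:
        Vt[2, :] = -Vt[2, :]
        s[2] = -s[2]
    return U, s, Vt


@njit(cache=False)
def sanitize_gradient(F):
    """Clamped elastic gradient for near-inverted/inverted states.

    Returns F itself when all signed singular values exceed the floor, else
    the rotation-consistent reconstruction with singular values clamped to
    EPS_J (forces stay finite and continuous across det F = 0).
    """
    U, s, Vt = _signed_svd(F)
    if s[0] >= EPS_J and s[1] >= EPS_J and s[2] >= EPS_J:
        return F.copy()
    sc = np.empty(3)
    for k in range(3):
        sc[k] = s[k] if s[k] > EPS_J else EPS_J
    return (U * sc) @ Vt


@njit(cache=False, fastmath=True)
def assemble_forces(
    pos,
    tets,
    Dminv,
    Vref,
    growth_normal,
    g_eff,
    mu,
    K,
    use_nodal_pressure,
    node_Vsum,
    forces,
    Jbar,
):
    """Internal elastic forces; returns (iso_energy, vol_energy, min_J).

    Isochoric neo-Hookean stress is evaluated elementwise on the elastic part
    Fe = F G^{-1}; the volumetric (J-1)^2 term uses nodal-averaged volume
    ratios (quarter-volume lumping) when ``use_nodal_pressure`` so linear tets
    do not lock.  Near-inverted elements are routed through the clamped SVD.
    """
    m = tets.shape[0]
    n = pos.shape[0]
    Fe_all = np.empty((m, 3, 3))
    Je_all = np.empty(m)
    Ds = np.empty((3, 3))
    Ginv = np.empty((3, 3))
    tmp = np.empty((3, 3))
    FeinvT = np.empty((3, 3))
    forces[:] = 0.0
    Jbar[:] = 0.0
    min_J = 1e300
    iso_energy = 0.0

    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        for r in range(3):
            Ds[r, 0] = pos[n1, r] - pos[n0, r]
            Ds[r, 1] = pos[n2, r] - pos[n0, r]
            Ds[r, 2] = pos[n3, r] - pos[n0, r]
        F = Ds @ Dminv[e]
        g = g_eff[e]
        nx, ny, nz = growth_normal[e, 0], growth_normal[e, 1], growth_normal[e, 2]
        ig = 1.0 / g
        c = 1.0 - ig
        # Ginv = (1/g) I + (1 - 1/g) n n^T
        Ginv[0, 0] = ig + c * nx * nx
        Ginv[0, 1] = c * nx * ny
        Ginv[0, 2] = c * nx * nz
        Ginv[1, 0] = Ginv[0, 1]
        Ginv[1, 1] = ig + c * ny * ny
        Ginv[1, 2] = c * ny * nz
        Ginv[2, 0] = Ginv[0, 2]
        Ginv[2, 1] = Ginv[1, 2]
        Ginv[2, 2] = ig + c * nz * nz
        Fe = F @ Ginv
        Je = _det3(Fe)
        if Je < min_J:
            min_J = Je
        # sigma_min >= Je / (sigma1 sigma2) >= 2 Je / I1, so the clamp can only
        # be active when Je < EPS_J * I1 / 2 (cheap exact gate for the SVD)
        I1g = 0.0
        for r in range(3):
            for cc in range(3):
                I1g += Fe[r, cc] * Fe[r, cc]
        if Je < 0.5 * EPS_J * I1g:
            Fe = sanitize_gradient(Fe)
            Je = _det3(Fe)
        Fe_all[e] = Fe
        Je_all[e] = Je
        # nodal-averaged volume ratio accumulation (reference-volume weights)
        w = Vref[e]
        Jw = w * Je
        Jbar[n0] += Jw
        Jbar[n1] += Jw
        Jbar[n2] += Jw
        Jbar[n3] += Jw

    for a in range(n):
        if node_Vsum[a] > 0.0:
            Jbar[a] /= node_Vsum[a]
        else:
            Jbar[a] = 1.0

    vol_energy = 0.0
    if use_nodal_pressure:
        for a in range(n):
            d = Jbar[a] - 1.0
            vol_energy += 0.5 * K * d * d * 0.25 * node_Vsum[a]

    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        Fe = Fe_all[e]
        Je = Je_all[e]
        _inv3(Fe, tmp)
        for r in range(3):
            for cc in range(3):
                FeinvT[r, cc] = tmp[cc, r]
        I1 = 0.0
        for r in range(3):
            for cc in range(3):
                I1 += Fe[r, cc] * Fe[r, cc]
        Jm23 = Je ** (-2.0 / 3.0)
        iso_energy += Vref[e] * 0.5 * mu * (I1 * Jm23 - 3.0)
        if use_nodal_pressure:
            pbar = 0.25 * K * (
                (Jbar[n0] - 1.0) + (Jbar[n1] - 1.0) + (Jbar[n2] - 1.0) + (Jbar[n3] - 1.0)
            )
        else:
            pbar = K * (Je - 1.0)
            vol_energy += Vref[e] * 0.5 * K * (Je - 1.0) ** 2
        # P = mu J^{-2/3} (Fe - I1/3 Fe^{-T}) + pbar * Je * Fe^{-T}
        coef = pbar * Je - mu * Jm23 * (I1 / 3.0)
        g = g_eff[e]
        nx, ny, nz = growth_normal[e, 0], growth_normal[e, 1], growth_normal[e, 2]
        ig = 1.0 / g
        c = 1.0 - ig
        Ginv[0, 0] = ig + c * nx * nx
        Ginv[0, 1] = c * nx * ny
        Ginv[0, 2] = c * nx * nz
        Ginv[1, 0] = Ginv[0, 1]
        Ginv[1, 1] = ig + c * ny * ny
        Ginv[1, 2] = c * ny * nz
        Ginv[2, 0] = Ginv[0, 2]
        Ginv[2, 1] = Ginv[1, 2]
        Ginv[2, 2] = ig + c * nz * nz
        # H = Vref * P (Dminv Ginv)^T ; note Ginv symmetric
        # P = mu*Jm23*Fe + coef*FeinvT
        for r in range(3):
            for cc in range(3):
                tmp[r, cc] = mu * Jm23 * Fe[r, cc] + coef * FeinvT[r, cc]
        # M = Dminv[e] @ Ginv  (3x3), H = Vref * tmp @ M^T
        P = tmp
        M = Dminv[e] @ Ginv
        fsum0 = 0.0
        fsum1 = 0.0
        fsum2 = 0.0
        for j in range(3):
            h0 = Vref[e] * (P[0, 0] * M[j, 0] + P[0, 1] * M[j, 1] + P[0, 2] * M[j, 2])
            h1 = Vref[e] * (P[1, 0] * M[j, 0] + P[1, 1] * M[j, 1] + P[1, 2] * M[j, 2])
            h2 = Vref[e] * (P[2, 0] * M[j, 0] + P[2, 1] * M[j, 1] + P[2, 2] * M[j, 2])
            node = tets[e, j + 1]
            forces[node, 0] -= h0
            forces[node, 1] -= h1
            forces[node, 2] -= h2
            fsum0 += h0
            fsum1 += h1
            fsum2 += h2
        forces[n0, 0] += fsum0
        forces[n0, 1] += fsum1
        forces[n0, 2] += fsum2

    return iso_energy, vol_energy, min_J


@njit(cache=False, fastmath=True)
def _hash_key(ix, iy, iz):
    return np.int64(ix) * np.int64(73856093) ^ np.int64(iy) * np.int64(19349663) ^ np.int64(iz) * np.int64(83492791)


@njit(cache=False, fastmath=True)
def _closest_point_tri(p, a, b, c):
    """Closest point on triangle abc to p (Ericson's algorithm)."""
    ab0 = b[0] - a[0]
    ab1 = b[1] - a[1]
    ab2 = b[2] - a[2]
    ac0 = c[0] - a[0]
    ac1 = c[1] - a[1]
    ac2 = c[2] - a[2]
    ap0 = p[0] - a[0]
    ap1 = p[1] - a[1]
    ap2 = p[2] - a[2]
    d1 = ab0 * ap0 + ab1 * ap1 + ab2 * ap2
    d2 = ac0 * ap0 + ac1 * ap1 + ac2 * ap2
    if d1 <= 0.0 and d2 <= 0.0:
        return a[0], a[1], a[2], 1.0, 0.0, 0.0
    bp0 = p[0] - b[0]
    bp1 = p[1] - b[1]
    bp2 = p[2] - b[2]
    d3 = ab0 * bp0 + ab1 * bp1 + ab2 * bp2
    d4 = ac0 * bp0 + ac1 * bp1 + ac2 * bp2
    if d3 >= 0.0 and d4 <= d3:
        return b[0], b[1], b[2], 0.0, 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a[0] + v * ab0, a[1] + v * ab1, a[2] + v * ab2, 1.0 - v, v, 0.0
    cp0 = p[0] - c[0]
    cp1 = p[1] - c[1]
    cp2 = p[2] - c[2]
    d5 = ab0 * cp0 + ab1 * cp1 + ab2 * cp2
    d6 = ac0 * cp0 + ac1 * cp1 + ac2 * cp2
    if d6 >= 0.0 and d5 <= d6:
        return c[0], c[1], c[2], 0.0, 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a[0] + w * ac0, a[1] + w * ac1, a[2] + w * ac2, 1.0 - w, 0.0, w
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (
            b[0] + w * (c[0] - b[0]),
            b[1] + w * (c[1] - b[1]),
            b[2] + w * (c[2] - b[2]),
            0.0,
            1.0 - w,
            w,
        )
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (
        a[0] + ab0 * v + ac0 * w,
        a[1] + ab1 * v + ac1 * w,
        a[2] + ab2 * v + ac2 * w,
        1.0 - v - w,
        v,
        w,
    )


@njit(cache=False, fastmath=True)
def contact_forces(
    pos,
    surf_verts,
    surf_tris,
    excl_indptr,
    excl_tris,
    cutoff,
    stiffness,
    cell_size,
    forces,
):
    """Penalty vertex-triangle self-contact; returns (max_penetration, energy).

    Triangles are hashed into the uniform cells overlapped by their bounding
    box expanded by the cutoff; each surface vertex queries its own cell.  A
    vertex within ``cutoff`` of a topologically non-adjacent triangle receives
    a linear penalty force k (cutoff - d) pushing it away from the triangle,
    with the opposite force spread on the triangle nodes by barycentric
    weights (action-reaction holds exactly).
    """
    nt = surf_tris.shape[0]
    inv_cs = 1.0 / cell_size
    # count entries
    total = 0
    for t in range(nt):
        xmin = 1e300
        xmax = -1e300
        ymin = 1e300
        ymax = -1e300
        zmin = 1e300
        zmax = -1e300
        for k in range(3):
            v = surf_tris[t, k]
            x = pos[v, 0]
            y = pos[v, 1]
            z = pos[v, 2]
            if x < xmin:
                xmin = x
            if x > xmax:
                xmax = x
            if y < ymin:
                ymin = y
            if y > ymax:
                ymax = y
            if z < zmin:
                zmin = z
            if z > zmax:
                zmax = z
        ix0 = int(np.floor((xmin - cutoff) * inv_cs))
        ix1 = int(np.floor((xmax + cutoff) * inv_cs))
        iy0 = int(np.floor((ymin - cutoff) * inv_cs))
        iy1 = int(np.floor((ymax + cutoff) * inv_cs))
        iz0 = int(np.floor((zmin - cutoff) * inv_cs))
        iz1 = int(np.floor((zmax + cutoff) * inv_cs))
        total += (ix1 - ix0 + 1) * (iy1 - iy0 + 1) * (iz1 - iz0 + 1)

    keys = np.empty(total, dtype=np.int64)
    tri_ids = np.empty(total, dtype=np.int64)
    idx = 0
    for t in range(nt):
        xmin = 1e300
        xmax = -1e300
        ymin = 1e300
        ymax = -1e300
        zmin = 1e300
        zmax = -1e300
        for k in range(3):
            v = surf_tris[t, k]
            x = pos[v, 0]
            y = pos[v, 1]
            z = pos[v, 2]
            if x < xmin:
                xmin = x
            if x > xmax:
                xmax = x
            if y < ymin:
                ymin = y
            if y > ymax:
                ymax = y
            if z < zmin:
                zmin = z
            if z > zmax:
                zmax = z
        ix0 = int(np.floor((xmin - cutoff) * inv_cs))
        ix1 = int(np.floor((xmax + cutoff) * inv_cs))
        iy0 = int(np.floor((ymin - cutoff) * inv_cs))
        iy1 = int(np.floor((ymax + cutoff) * inv_cs))
        iz0 = int(np.floor((zmin - cutoff) * inv_cs))
        iz1 = int(np.floor((zmax + cutoff) * inv_cs))
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                for iz in range(iz0, iz1 + 1):
                    keys[idx] = _hash_key(ix, iy, iz)
                    tri_ids[idx] = t
                    idx += 1

    order = np.argsort(keys)
    keys_sorted = keys[order]
    tris_sorted = tri_ids[order]

    max_pen = 0.0
    energy = 0.0
    pvec = np.empty(3)
    for si in range(surf_verts.shape[0]):
        v = surf_verts[si]
        pvec[0] = pos[v, 0]
        pvec[1] = pos[v, 1]
        pvec[2] = pos[v, 2]
        ix = int(np.floor(pvec[0] * inv_cs))
        iy = int(np.floor(pvec[1] * inv_cs))
        iz = int(np.floor(pvec[2] * inv_cs))
        key = _hash_key(ix, iy, iz)
        lo = np.searchsorted(keys_sorted, key, side="left")
        hi = np.searchsorted(keys_sorted, key, side="right")
        for q in range(lo, hi):
            t = tris_sorted[q]
            # skip topologically adjacent triangles
            excluded = False
            for r in range(excl_indptr[si], excl_indptr[si + 1]):
                if excl_tris[r] == t:
                    excluded = True
                    break
            if excluded:
                continue
            a = pos[surf_tris[t, 0]]
            b = pos[surf_tris[t, 1]]
            c = pos[surf_tris[t, 2]]
            cx, cy, cz, w0, w1, w2 = _closest_point_tri(pvec, a, b, c)
            dx = pvec[0] - cx
            dy = pvec[1] - cy
            dz = pvec[2] - cz
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= cutoff or d < 1e-14:
                continue
            pen = cutoff - d
            if pen > max_pen:
                max_pen = pen
            fmag = stiffness * pen
            energy += 0.5 * stiffness * pen * pen
            fx = fmag * dx / d
            fy = fmag * dy / d
            fz = fmag * dz / d
            forces[v, 0] += fx
            forces[v, 1] += fy
            forces[v, 2] += fz
            for k in range(3):
                w = w0 if k == 0 else (w1 if k == 1 else w2)
                node = surf_tris[t, k]
                forces[node, 0] -= w * fx
                forces[node, 1] -= w * fy
                forces[node, 2] -= w * fz
    return max_pen, energy


@njit(cache=False, fastmath=True)
def nearest_boundary_brute(points, tri_pts):
    """Exact nearest boundary triangle per point.

    Full scan over triangles with a centroid/circumradius lower bound to skip
    triangles that cannot beat the current minimum; exact where not skipped.
    """
    n_t = tri_pts.shape[0]
    n_p = points.shape[0]
    cent = np.empty((n_t, 3))
    rad = np.empty(n_t)
    for t in range(n_t):
        for j in range(3):
            cent[t, j] = (tri_pts[t, 0, j] + tri_pts[t, 1, j] + tri_pts[t, 2, j]) / 3.0
        r2 = 0.0
        for k in range(3):
            d2 = 0.0
            for j in range(3):
                dd = tri_pts[t, k, j] - cent[t, j]
                d2 += dd * dd
            if d2 > r2:
                r2 = d2
        rad[t] = np.sqrt(r2)
    dists = np.empty(n_p)
    idx = np.empty(n_p, dtype=np.int64)
    p = np.empty(3)
    for i in range(n_p):
        p[0] = points[i, 0]
        p[1] = points[i, 1]
        p[2] = points[i, 2]
        best = 1e300
        best_t = -1
        for t in range(n_t):
            dc = 0.0
            for j in range(3):
                dd = p[j] - cent[t, j]
                dc += dd * dd
            lb = np.sqrt(dc) - rad[t]
            if lb >= best:
                continue
            cx, cy, cz, w0, w1, w2 = _closest_point_tri(
                p, tri_pts[t, 0], tri_pts[t, 1], tri_pts[t, 2]
            )
            d2 = (p[0] - cx) ** 2 + (p[1] - cy) ** 2 + (p[2] - cz) ** 2
            d = np.sqrt(d2)
            if d < best:
                best = d
                best_t = t
        dists[i] = best
        idx[i] = best_t
    return dists, idx


@njit(cache=False, fastmath=True)
def find_contact_pairs(
    pos, surf_verts, surf_tris, excl_indptr, excl_tris, search_radius, cell_size
):
    """Vertex-triangle candidate pairs within ``search_radius`` (spatial hash).

    Detection with a radius larger than the force cutoff lets the pair list be
    reused over several steps while nodes move less than the margin.
    """
    nt = surf_tris.shape[0]
    inv_cs = 1.0 / cell_size
    total = 0
    for t in range(nt):
        xmin = 1e300; xmax = -1e300; ymin = 1e300; ymax = -1e300; zmin = 1e300; zmax = -1e300
        for k in range(3):
            v = surf_tris[t, k]
            x = pos[v, 0]; y = pos[v, 1]; z = pos[v, 2]
            if x < xmin: xmin = x
            if x > xmax: xmax = x
            if y < ymin: ymin = y
            if y > ymax: ymax = y
            if z < zmin: zmin = z
            if z > zmax: zmax = z
        ix0 = int(np.floor((xmin - search_radius) * inv_cs)); ix1 = int(np.floor((xmax + search_radius) * inv_cs))
        iy0 = int(np.floor((ymin - search_radius) * inv_cs)); iy1 = int(np.floor((ymax + search_radius) * inv_cs))
        iz0 = int(np.floor((zmin - search_radius) * inv_cs)); iz1 = int(np.floor((zmax + search_radius) * inv_cs))
        total += (ix1 - ix0 + 1) * (iy1 - iy0 + 1) * (iz1 - iz0 + 1)
    keys = np.empty(total, dtype=np.int64)
    tri_ids = np.empty(total, dtype=np.int64)
    idx = 0
    for t in range(nt):
        xmin = 1e300; xmax = -1e300; ymin = 1e300; ymax = -1e300; zmin = 1e300; zmax = -1e300
        for k in range(3):
            v = surf_tris[t, k]
            x = pos[v, 0]; y = pos[v, 1]; z = pos[v, 2]
            if x < xmin: xmin = x
            if x > xmax: xmax = x
            if y < ymin: ymin = y
            if y > ymax: ymax = y
            if z < zmin: zmin = z
            if z > zmax: zmax = z
        ix0 = int(np.floor((xmin - search_radius) * inv_cs)); ix1 = int(np.floor((xmax + search_radius) * inv_cs))
        iy0 = int(np.floor((ymin - search_radius) * inv_cs)); iy1 = int(np.floor((ymax + search_radius) * inv_cs))
        iz0 = int(np.floor((zmin - search_radius) * inv_cs)); iz1 = int(np.floor((zmax + search_radius) * inv_cs))
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                for iz in range(iz0, iz1 + 1):
                    keys[idx] = _hash_key(ix, iy, iz)
                    tri_ids[idx] = t
                    idx += 1
    order = np.argsort(keys)
    keys_sorted = keys[order]
    tris_sorted = tri_ids[order]

    cap = 16 * surf_verts.shape[0]
    pv = np.empty(cap, dtype=np.int64)
    pt = np.empty(cap, dtype=np.int64)
    count = 0
    p = np.empty(3)
    for si in range(surf_verts.shape[0]):
        v = surf_verts[si]
        p[0] = pos[v, 0]; p[1] = pos[v, 1]; p[2] = pos[v, 2]
        key = _hash_key(int(np.floor(p[0] * inv_cs)), int(np.floor(p[1] * inv_cs)), int(np.floor(p[2] * inv_cs)))
        lo = np.searchsorted(keys_sorted, key, side="left")
        hi = np.searchsorted(keys_sorted, key, side="right")
        for q in range(lo, hi):
            t = tris_sorted[q]
            excluded = False
            for r in range(excl_indptr[si], excl_indptr[si + 1]):
                if excl_tris[r] == t:
                    excluded = True
                    break
            if excluded:
                continue
            a = pos[surf_tris[t, 0]]
            b = pos[surf_tris[t, 1]]
            c = pos[surf_tris[t, 2]]
            cx, cy, cz, w0, w1, w2 = _closest_point_tri(p, a, b, c)
            d2 = (p[0] - cx) ** 2 + (p[1] - cy) ** 2 + (p[2] - cz) ** 2
            if d2 < search_radius * search_radius:
                if count >= cap:
                    pv2 = np.empty(2 * cap, dtype=np.int64)
                    pt2 = np.empty(2 * cap, dtype=np.int64)
                    pv2[:cap] = pv
                    pt2[:cap] = pt
                    pv = pv2
                    pt = pt2
                    cap *= 2
                pv[count] = v
                pt[count] = t
                count += 1
    return pv[:count], pt[:count]


@njit(cache=False, fastmath=True)
def pair_contact_forces(pos, pair_v, pair_t, surf_tris, cutoff, stiffness, forces):
    """Penalty forces for a cached candidate pair list; returns (max_pen, energy)."""
    max_pen = 0.0
    energy = 0.0
    p = np.empty(3)
    for q in range(pair_v.shape[0]):
        v = pair_v[q]
        t = pair_t[q]
        p[0] = pos[v, 0]; p[1] = pos[v, 1]; p[2] = pos[v, 2]
        a = pos[surf_tris[t, 0]]
        b = pos[surf_tris[t, 1]]
        c = pos[surf_tris[t, 2]]
        cx, cy, cz, w0, w1, w2 = _closest_point_tri(p, a, b, c)
        dx = p[0] - cx; dy = p[1] - cy; dz = p[2] - cz
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= cutoff or d < 1e-14:
            continue
        pen = cutoff - d
        if pen > max_pen:
            max_pen = pen
        fmag = stiffness * pen
        energy += 0.5 * stiffness * pen * pen
        fx = fmag * dx / d; fy = fmag * dy / d; fz = fmag * dz / d
        forces[v, 0] += fx; forces[v, 1] += fy; forces[v, 2] += fz
        for k in range(3):
            w = w0 if k == 0 else (w1 if k == 1 else w2)
            node = surf_tris[t, k]
            forces[node, 0] -= w * fx
            forces[node, 1] -= w * fy
            forces[node, 2] -= w * fz
    return max_pen, energy
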