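"""Numba kernels for the inner loops of the energy model.

All arrays are float64, coordinates in Å, energies in kJ/mol.  The kernels
are deterministic: SASA point sets are fixed deterministic constructions and
all reductions run in a fixed order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "golden_spiral_points",
    "symmetric_sphere_points",
    "sasa_areas",
    "pair_scan",
    "neighbor_csr",
    "evaluate_pose_kernel",
]


def symmetric_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform sphere point set with exact 6-fold
    azimuthal symmetry.

    Points sit on latitude rings (ring populations proportional to the ring
    circumference, rounded to multiples of 6), so rotating the set by any
    multiple of 60 degrees about z maps it onto itself.  This makes
    point-sampled SASA exactly invariant under the honeycomb lattice's
    point-group rotations.  The returned count is the closest achievable to
    ``n`` (area normalization uses the actual count).
    """
    if n < 32:
        raise ValueError("n_sphere_points must be >= 32")
    n_rings = max(3, int(round(np.sqrt(n * np.pi) / 2.0)))
    theta = np.pi * (np.arange(n_rings) + 0.5) / n_rings
    weights = np.sin(theta)
    ideal = n * weights / weights.sum()
    counts = np.maximum(6, 6 * np.round(ideal / 6.0).astype(int))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    rings = []
    for k in range(n_rings):
        m = counts[k]
        phi = golden * k + 2.0 * np.pi * np.arange(m) / m
        ring = np.empty((m, 3))
        ring[:, 0] = np.sin(theta[k]) * np.cos(phi)
        ring[:, 1] = np.sin(theta[k]) * np.sin(phi)
        ring[:, 2] = np.cos(theta[k])
        rings.append(ring)
    return np.concatenate(rings)


def neighbor_csr(
    pos: np.ndarray, radii: np.ndarray, probe: float, smoothing: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """CSR occlusion-neighbor lists for a rigid atom set.

    Atom j is an occlusion neighbor of i when their solvent-expanded spheres
    intersect (d < r_i + r_j + 2*probe, extended by the burial smoothing
    band).  Lists are sorted by distance so the burial test in the SASA
    kernel exits early.  Valid for any rigid motion of the set, so they are
    precomputed once per molecule.
    """
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = (diff * diff).sum(axis=2)
    cut = radii[:, None] + radii[None, :] + 2.0 * probe + smoothing
    adj = d2 < cut * cut
    np.fill_diagonal(adj, False)
    indptr = np.zeros(n + 1, dtype=np.int64)
    cols = []
    for i in range(n):
        idx = np.nonzero(adj[i])[0]
        idx = idx[np.argsort(d2[i, idx], kind="stable")]
        cols.append(idx)
        indptr[i + 1] = indptr[i] + len(idx)
    indices = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    return indices.astype(np.int64), indptr


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    if n < 32:
        raise ValueError("n_sphere_points must be >= 32")
    k = np.arange(n, dtype=np.float64) + 0.5
    z = 1.0 - 2.0 * k / n
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    pts = np.empty((n, 3))
    pts[:, 0] = np.sin(theta) * np.cos(phi)
    pts[:, 1] = np.sin(theta) * np.sin(phi)
    pts[:, 2] = z
    return pts


@njit(inline="always")
def _exposure_weight(d2, r_exp, smoothing):
    """Soft indicator that a test point is outside a neighbor sphere.

    With ``smoothing == 0`` this is the exact binary Shrake-Rupley test.
    Otherwise a cubic smoothstep ramps the indicator across a band of width
    ``smoothing`` centered on the sphere boundary, making point-sampled areas
    continuous in the atomic coordinates.
    """
    if smoothing <= 0.0:
        if d2 < r_exp * r_exp:
            return 0.0
        return 1.0
    d = np.sqrt(d2)
    t = (d - (r_exp - 0.5 * smoothing)) / smoothing
    if t <= 0.0:
        return 0.0
    if t >= 1.0:
        return 1.0
    return t * t * (3.0 - 2.0 * t)


@njit(cache=True)
def sasa_areas(pos, radii, probe, points, compute_mask, smoothing=0.0):
    """Shrake-Rupley per-atom solvent accessible surface area.

    For every atom with ``compute_mask`` set, counts the fraction of test
    points on its solvent-expanded sphere (radius + probe) that are not
    strictly inside any other expanded sphere.  Atoms with identical centers
    do not occlude each other (a point at exactly the neighbor's expanded
    radius is on, not inside, that sphere), so coincident atoms are handled
    without special casing.  Masked-out atoms get area 0 and are still used
    as occluders.  ``smoothing`` > 0 replaces the binary burial test with a
    smoothstep band of that width (Å) about each sphere boundary.
    """
    n = pos.shape[0]
    n_pts = points.shape[0]
    exp_r = radii + probe
    areas = np.zeros(n)
    nb_idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        if not compute_mask[i]:
            continue
        ri = exp_r[i]
        n_nb = 0
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            rc = ri + exp_r[j] + smoothing
            if dx * dx + dy * dy + dz * dz < rc * rc:
                nb_idx[n_nb] = j
                n_nb += 1
        acc = 0.0
        for p in range(n_pts):
            px = xi + ri * points[p, 0]
            py = yi + ri * points[p, 1]
            pz = zi + ri * points[p, 2]
            w = 1.0
            for k in range(n_nb):
                j = nb_idx[k]
                dx = px - pos[j, 0]
                dy = py - pos[j, 1]
                dz = pz - pos[j, 2]
                w *= _exposure_weight(dx * dx + dy * dy + dz * dz, exp_r[j], smoothing)
                if w == 0.0:
                    break
            acc += w
        areas[i] = 4.0 * np.pi * ri * ri * acc / n_pts
    return areas


@njit(cache=True)
def pair_scan(ppos, peps, prmin_half, prad,
              spos, s_eps, s_rmin_half, s_rad,
              cutoff, probe):
    """One pass over all protein-surface atom pairs.

    Returns ``(vdw, min_dist, occluded_flags, coincident)``:

    * ``vdw`` — Lennard-Jones 12-6 sum (CHARMM combining: geometric-mean
      epsilon, summed Rmin/2) over pairs closer than ``cutoff``;
    * ``min_dist`` — smallest protein-surface atom distance;
    * ``occluded_flags`` — per surface atom, whether any protein atom is
      close enough (< r_i + r_j + 2*probe) to change its SASA;
    * ``coincident`` — True when a pair distance is exactly zero (broken pose).
    """
    n_p = ppos.shape[0]
    n_s = spos.shape[0]
    cutoff2 = cutoff * cutoff
    vdw = 0.0
    min_d2 = 1.0e30
    coincident = False
    flags = np.zeros(n_s, dtype=np.bool_)
    for j in range(n_s):
        xj, yj, zj = spos[j, 0], spos[j, 1], spos[j, 2]
        eps_j = s_eps[j]
        rh_j = s_rmin_half[j]
        for i in range(n_p):
            dx = ppos[i, 0] - xj
            dy = ppos[i, 1] - yj
            dz = ppos[i, 2] - zj
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < min_d2:
                min_d2 = d2
            if d2 == 0.0:
                coincident = True
                continue
            occ = prad[i] + s_rad[j] + 2.0 * probe
            if d2 < occ * occ:
                flags[j] = True
            if d2 < cutoff2:
                rmin = prmin_half[i] + rh_j
                s6 = (rmin * rmin / d2) ** 3
                vdw += np.sqrt(peps[i] * eps_j) * (s6 * s6 - 2.0 * s6)
    return vdw, np.sqrt(min_d2), flags, coincident


@njit(cache=True)
def evaluate_pose_kernel(
    ppos, peps, prmin_half, prad,
    p_nb_idx, p_nb_ptr,
    spos, s_eps, s_rmin_half, s_rad,
    s_nb_idx, s_nb_ptr,
    cutoff, probe, smoothing, p_points, s_points,
):
    """Fused single-pose evaluation: VDW sum, min distance and SASA.

    Intramolecular occlusion neighbors for the protein and the surface patch
    are precomputed CSR lists (rigid bodies, see :func:`neighbor_csr`); only
    the protein-surface cross pairs are discovered here, in the same pass
    that accumulates the Lennard-Jones sum.  Returns
    ``(vdw, min_dist, protein_areas, surface_areas, flags, coincident)``
    where ``surface_areas`` is filled only for flagged (protein-perturbed)
    surface atoms.
    """
    n_p = ppos.shape[0]
    n_s = spos.shape[0]
    n_p_pts = p_points.shape[0]
    n_s_pts = s_points.shape[0]
    cutoff2 = cutoff * cutoff
    max_cross = 96
    cross_ps = np.empty((n_p, max_cross), dtype=np.int64)
    cross_ps_n = np.zeros(n_p, dtype=np.int64)
    cross_sp = np.empty((n_s, max_cross), dtype=np.int64)
    cross_sp_n = np.zeros(n_s, dtype=np.int64)
    vdw = 0.0
    min_d2 = 1.0e30
    coincident = False
    for j in range(n_s):
        xj, yj, zj = spos[j, 0], spos[j, 1], spos[j, 2]
        for i in range(n_p):
            dx = ppos[i, 0] - xj
            dy = ppos[i, 1] - yj
            dz = ppos[i, 2] - zj
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < min_d2:
                min_d2 = d2
            if d2 == 0.0:
                coincident = True
                continue
            occ = prad[i] + s_rad[j] + 2.0 * probe + smoothing
            if d2 < occ * occ:
                if cross_ps_n[i] < max_cross:
                    cross_ps[i, cross_ps_n[i]] = j
                    cross_ps_n[i] += 1
                if cross_sp_n[j] < max_cross:
                    cross_sp[j, cross_sp_n[j]] = i
                    cross_sp_n[j] += 1
            if d2 < cutoff2:
                rmin = prmin_half[i] + s_rmin_half[j]
                s6 = (rmin * rmin / d2) ** 3
                vdw += np.sqrt(peps[i] * s_eps[j]) * (s6 * s6 - 2.0 * s6)

    p_exp = prad + probe
    s_exp = s_rad + probe
    p_areas = np.zeros(n_p)
    for i in range(n_p):
        ri = p_exp[i]
        acc = 0.0
        xi, yi, zi = ppos[i, 0], ppos[i, 1], ppos[i, 2]
        for p in range(n_p_pts):
            px = xi + ri * p_points[p, 0]
            py = yi + ri * p_points[p, 1]
            pz = zi + ri * p_points[p, 2]
            w = 1.0
            for k in range(p_nb_ptr[i], p_nb_ptr[i + 1]):
                jn = p_nb_idx[k]
                dx = px - ppos[jn, 0]
                dy = py - ppos[jn, 1]
                dz = pz - ppos[jn, 2]
                w *= _exposure_weight(dx * dx + dy * dy + dz * dz, p_exp[jn], smoothing)
                if w == 0.0:
                    break
            if w > 0.0:
                for k in range(cross_ps_n[i]):
                    jn = cross_ps[i, k]
                    dx = px - spos[jn, 0]
                    dy = py - spos[jn, 1]
                    dz = pz - spos[jn, 2]
                    w *= _exposure_weight(dx * dx + dy * dy + dz * dz, s_exp[jn], smoothing)
                    if w == 0.0:
                        break
            acc += w
        p_areas[i] = 4.0 * np.pi * ri * ri * acc / n_p_pts

    s_areas = np.zeros(n_s)
    flags = cross_sp_n > 0
    for j in range(n_s):
        if cross_sp_n[j] == 0:
            continue
        rj = s_exp[j]
        acc = 0.0
        xj, yj, zj = spos[j, 0], spos[j, 1], spos[j, 2]
        for p in range(n_s_pts):
            px = xj + rj * s_points[p, 0]
            py = yj + rj * s_points[p, 1]
            pz = zj + rj * s_points[p, 2]
            w = 1.0
            for k in range(s_nb_ptr[j], s_nb_ptr[j + 1]):
                jn = s_nb_idx[k]
                dx = px - spos[jn, 0]
                dy = py - spos[jn, 1]
                dz = pz - spos[jn, 2]
                w *= _exposure_weight(dx * dx + dy * dy + dz * dz, s_exp[jn], smoothing)
                if w == 0.0:
                    break
            if w > 0.0:
                for k in range(cross_sp_n[j]):
                    jn = cross_sp[j, k]
                    dx = px - ppos[jn, 0]
                    dy = py - ppos[jn, 1]
                    dz = pz - ppos[jn, 2]
                    w *= _exposure_weight(dx * dx + dy * dy + dz * dz, p_exp[jn], smoothing)
                    if w == 0.0:
                        break
            acc += w
        s_areas[j] = 4.0 * np.pi * rj * rj * acc / n_s_pts
    return vdw, np.sqrt(min_d2), p_areas, s_areas, flags, coincident
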