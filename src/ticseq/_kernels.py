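"""Grid counting kernels for cross-sectional free-area computation.

The y=0 cross-section is discretised on a fixed lattice of square cells
anchored at the channel axis (cell centers at (k + 0.5) * step).  A cell is
free when it lies inside the accessible window (disk of radius D clipped to
|z| <= z_window) and outside every atom's inflated sphere sliced by the
plane.  The same enumeration is used by the numba kernel and the numpy
fallback, so both count identical cells.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _centers_in(lo, hi, step):  # pragma: no cover
    """Number of lattice centers (j + 0.5) * step in the closed [lo, hi]."""
    j_lo = int(np.ceil(lo / step - 0.5))
    j_hi = int(np.floor(hi / step - 0.5))
    return j_hi - j_lo + 1 if j_hi >= j_lo else 0


@njit(cache=True)
def _count_free_loop(cx, cz, rc2, disk_radius, z_window, step):  # pragma: no cover
    """Free-cell count via a column scanline.

    For each x-column of lattice centers, the window is a closed z-interval
    and every slice circle covers a closed z-interval; free cells are window
    centers outside the merged union.  Equivalent to testing every cell
    center, cheaper by the column height.
    """
    n = int(np.ceil(disk_radius / step))
    d2 = disk_radius * disk_radius
    ncirc = cx.shape[0]
    lo_arr = np.empty(ncirc)
    hi_arr = np.empty(ncirc)
    free = 0
    for i in range(-n, n):
        x = (i + 0.5) * step
        x2 = x * x
        if x2 > d2:
            continue
        zmax = np.sqrt(d2 - x2)
        if z_window < zmax:
            zmax = z_window
        if zmax < 0.0:
            continue
        total = _centers_in(-zmax, zmax, step)
        if total == 0:
            continue
        # clipped coverage intervals of this column
        m = 0
        for a in range(ncirc):
            dx = x - cx[a]
            h2 = rc2[a] - dx * dx
            if h2 < 0.0:
                continue
            h = np.sqrt(h2)
            lo = cz[a] - h
            hi = cz[a] + h
            if lo < -zmax:
                lo = -zmax
            if hi > zmax:
                hi = zmax
            if hi < lo:
                continue
            lo_arr[m] = lo
            hi_arr[m] = hi
            m += 1
        if m == 0:
            free += total
            continue
        # insertion sort by interval start, then merge and count
        for a in range(1, m):
            key_lo = lo_arr[a]
            key_hi = hi_arr[a]
            b = a - 1
            while b >= 0 and lo_arr[b] > key_lo:
                lo_arr[b + 1] = lo_arr[b]
                hi_arr[b + 1] = hi_arr[b]
                b -= 1
            lo_arr[b + 1] = key_lo
            hi_arr[b + 1] = key_hi
        covered = 0
        cur_lo = lo_arr[0]
        cur_hi = hi_arr[0]
        for a in range(1, m):
            if lo_arr[a] <= cur_hi:
                if hi_arr[a] > cur_hi:
                    cur_hi = hi_arr[a]
            else:
                covered += _centers_in(cur_lo, cur_hi, step)
                cur_lo = lo_arr[a]
                cur_hi = hi_arr[a]
        covered += _centers_in(cur_lo, cur_hi, step)
        free += total - covered
    return free


def _count_free_numpy(cx, cz, rc2, disk_radius, z_window, step):
    n = int(np.ceil(disk_radius / step))
    nz = int(np.ceil(min(disk_radius, z_window) / step))
    x = (np.arange(-n, n) + 0.5) * step
    z = (np.arange(-nz, nz) + 0.5) * step
    X, Z = np.meshgrid(x, z, indexing="ij")
    inside = (X**2 + Z**2 <= disk_radius**2) & (np.abs(Z) <= z_window)
    covered = np.zeros_like(inside)
    for a in range(len(cx)):
        covered |= (X - cx[a]) ** 2 + (Z - cz[a]) ** 2 <= rc2[a]
    return int(np.count_nonzero(inside & ~covered))


@njit(cache=True)
def _rodrigues(axis, angle_deg):  # pragma: no cover
    ux, uy, uz = axis
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / norm, uy / norm, uz / norm
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    R = np.empty((3, 3))
    R[0, 0] = c + ux * ux * (1 - c)
    R[0, 1] = ux * uy * (1 - c) - uz * s
    R[0, 2] = ux * uz * (1 - c) + uy * s
    R[1, 0] = uy * ux * (1 - c) + uz * s
    R[1, 1] = c + uy * uy * (1 - c)
    R[1, 2] = uy * uz * (1 - c) - ux * s
    R[2, 0] = uz * ux * (1 - c) - uy * s
    R[2, 1] = uz * uy * (1 - c) + ux * s
    R[2, 2] = c + uz * uz * (1 - c)
    return R


@njit(cache=True)
def _rotate_subset(P, idx, origin, R):  # pragma: no cover
    for t in range(idx.shape[0]):
        a = idx[t]
        x = P[a, 0] - origin[0]
        y = P[a, 1] - origin[1]
        z = P[a, 2] - origin[2]
        P[a, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + origin[0]
        P[a, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + origin[1]
        P[a, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + origin[2]


@njit(cache=True)
def _free_area_posed(P, radii, inflate, disk_radius, z_window, step):  # pragma: no cover
    n_atoms = P.shape[0]
    cx = np.empty(n_atoms)
    cz = np.empty(n_atoms)
    rc2 = np.empty(n_atoms)
    m = 0
    for a in range(n_atoms):
        r = radii[a] + inflate
        if abs(P[a, 1]) < r:
            cx[m] = P[a, 0]
            cz[m] = P[a, 2]
            rc2[m] = r * r - P[a, 1] * P[a, 1]
            m += 1
    return _count_free_loop(cx[:m], cz[:m], rc2[:m], disk_radius, z_window, step) \
        * step * step


@njit(cache=True)
def mc_free_areas(coords, radii, phi_idx, psi_idx, i_n, i_ca, i_c,
                  dphi, dpsi, azimuth, inflate_a, inflate_b,
                  disk_radius, z_window, step):  # pragma: no cover
    """Free y=0 window areas for a batch of posed conformations.

    Mirrors apply_conformation + plane_exclusion_area: phi partition rotates
    about the CA->N axis through N, psi partition about CA->C through C,
    then the whole residue about z by the azimuth.  Returns (n, 2) areas for
    the two inflation radii.
    """
    n = dphi.shape[0]
    out = np.empty((n, 2))
    ez = np.array([0.0, 0.0, 1.0])
    for k in range(n):
        P = coords.copy()
        if i_n >= 0 and phi_idx.shape[0] > 0 and dphi[k] != 0.0:
            axis = P[i_n] - P[i_ca]
            R = _rodrigues(axis, dphi[k])
            _rotate_subset(P, phi_idx, P[i_n].copy(), R)
        if i_c >= 0 and psi_idx.shape[0] > 0 and dpsi[k] != 0.0:
            axis = P[i_c] - P[i_ca]
            R = _rodrigues(axis, dpsi[k])
            _rotate_subset(P, psi_idx, P[i_c].copy(), R)
        if azimuth[k] != 0.0:
            Rz = _rodrigues(ez, azimuth[k])
            all_idx = np.arange(P.shape[0])
            _rotate_subset(P, all_idx, np.zeros(3), Rz)
        out[k, 0] = _free_area_posed(P, radii, inflate_a, disk_radius, z_window, step)
        out[k, 1] = _free_area_posed(P, radii, inflate_b, disk_radius, z_window, step)
    return out


HAVE_NUMBA = _HAVE_NUMBA


def slice_circles(coords: np.ndarray, radii: np.ndarray):
    """Circles cut in the y=0 plane by spheres (centers, radii).

    Returns (cx, cz, rc2) for the spheres that actually intersect the plane.
    """
    if len(radii) == 0:
        e = np.empty(0)
        return e, e, e
    y = coords[:, 1]
    sel = np.abs(y) < radii
    rc2 = radii[sel] ** 2 - y[sel] ** 2
    return (
        np.ascontiguousarray(coords[sel, 0]),
        np.ascontiguousarray(coords[sel, 2]),
        np.ascontiguousarray(rc2),
    )


def count_free_cells(coords, radii, disk_radius, z_window, step,
                     force_numpy: bool = False) -> int:
    """Number of free lattice cells in the clipped y=0 window."""
    cx, cz, rc2 = slice_circles(np.asarray(coords, dtype=float).reshape(-1, 3),
                                np.asarray(radii, dtype=float).reshape(-1))
    if _HAVE_NUMBA and not force_numpy:
        return int(_count_free_loop(cx, cz, rc2,
                                    float(disk_radius), float(z_window), float(step)))
    return _count_free_numpy(cx, cz, rc2, float(disk_radius), float(z_window),
                             float(step))
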