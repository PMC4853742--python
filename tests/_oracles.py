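"""Independent brute-force oracles used to validate the geometry and
classification code.  These deliberately avoid the implementation's own
algorithms: ray marching instead of closed-form ray-sphere intersection,
rejection sampling instead of lattice counting, dense scanning instead of
bisection."""

from __future__ import annotations

import numpy as np


def ray_march_mean_radius(centers, radii, n_rays=100_000, seed=0, tol=1e-9):
    """Mean origin-to-surface distance by marching random rays inward.

    For each random direction, start beyond every sphere and bisect between
    a point known to be outside and one inside to locate the outermost
    surface crossing.
    """
    centers = np.atleast_2d(centers)
    radii = np.atleast_1d(radii)
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_rays, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    t_hi = float(np.max(np.linalg.norm(centers, axis=1) + radii)) + 1.0

    def inside(t, dirs):
        pts = dirs * t[:, None]
        dist = np.full(len(t), np.inf)
        for c, r in zip(centers, radii):
            np.minimum(dist, np.linalg.norm(pts - c, axis=1) - r, out=dist)
        return dist < 0

    # march inward in coarse steps until inside
    step = 0.05
    t_in = np.full(n_rays, t_hi)
    pending = np.ones(n_rays, dtype=bool)
    t = t_hi
    while t > 0 and pending.any():
        t -= step
        idx = np.nonzero(pending)[0]
        hit = inside(np.full(len(idx), max(t, 0.0)), d[idx])
        t_in[idx[hit]] = max(t, 0.0)
        pending[idx[hit]] = False
    if pending.any():
        raise RuntimeError("some rays never entered the union (origin outside?)")
    lo, hi = t_in, t_in + step
    while np.max(hi - lo) > tol:
        mid = (lo + hi) / 2.0
        is_in = inside(mid, d)
        lo = np.where(is_in, mid, lo)
        hi = np.where(is_in, hi, mid)
    return float(((lo + hi) / 2.0).mean())


def mc_shell_volume(centers, radii, r_lo, r_hi, n_points=10_000_000, seed=0):
    """Rejection-sampling volume of the proximal shell r_lo <= d < r_hi."""
    centers = np.atleast_2d(centers)
    radii = np.atleast_1d(radii)
    lo = centers.min(axis=0) - radii.max() - r_hi
    hi = centers.max(axis=0) + radii.max() + r_hi
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 1_000_000
    remaining = n_points
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        d = np.full(m, np.inf)
        for c, r in zip(centers, radii):
            np.minimum(d, np.linalg.norm(pts - c, axis=1) - r, out=d)
        hits += int(np.count_nonzero((d >= r_lo) & (d < r_hi)))
        remaining -= m
    return box_vol * hits / n_points


def mc_plane_free_area(centers, radii, inflate, disk_radius, z_window,
                       n_points=10_000_000, seed=0):
    """Rejection-sampling area of the free region of the y=0 window."""
    centers = np.atleast_2d(centers)
    radii = np.atleast_1d(radii) + inflate
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 1_000_000
    remaining = n_points
    while remaining > 0:
        m = min(chunk, remaining)
        x = rng.uniform(-disk_radius, disk_radius, m)
        z = rng.uniform(-disk_radius, disk_radius, m)
        ok = (x * x + z * z <= disk_radius**2) & (np.abs(z) <= z_window)
        for c, r in zip(centers, radii):
            if abs(c[1]) >= r:
                continue
            rc2 = r * r - c[1] * c[1]
            ok &= (x - c[0]) ** 2 + (z - c[2]) ** 2 > rc2
        hits += int(np.count_nonzero(ok))
        remaining -= m
    return (2 * disk_radius) ** 2 * hits / n_points


def mc_shell_plane_area(centers, radii, r_lo, r_hi, n_points=10_000_000, seed=0):
    """Rejection-sampling area of {surface distance in [r_lo, r_hi)} in y=0."""
    centers = np.atleast_2d(centers)
    radii = np.atleast_1d(radii)
    half = float(np.max(np.abs(centers[:, [0, 2]])) + radii.max() + r_hi + 0.5)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 1_000_000
    remaining = n_points
    while remaining > 0:
        m = min(chunk, remaining)
        x = rng.uniform(-half, half, m)
        z = rng.uniform(-half, half, m)
        d = np.full(m, np.inf)
        for c, r in zip(centers, radii):
            np.minimum(
                d,
                np.sqrt((x - c[0]) ** 2 + c[1] ** 2 + (z - c[2]) ** 2) - r,
                out=d,
            )
        hits += int(np.count_nonzero((d >= r_lo) & (d < r_hi)))
        remaining -= m
    return (2 * half) ** 2 * hits / n_points


def brute_force_effective_radius(areas, widths, edge_lo, r_upper, rhs,
                                 grid=1e-4):
    """Scan candidate radii on a dense grid for the area-balance root.

    Evaluates LHS(r) = sum over shells of the area beyond r by direct
    summation, returns the smallest candidate whose LHS is <= RHS (the
    balance crossing of the monotone non-increasing LHS).
    """
    candidates = np.arange(0.0, r_upper + grid, grid)
    areas = np.asarray(areas)
    widths = np.asarray(widths)
    edge_lo = np.asarray(edge_lo)
    edge_hi = edge_lo + widths
    for r in candidates:
        over = np.clip(np.minimum(edge_hi, r_upper) - np.maximum(edge_lo, r), 0.0, None)
        lhs = float(np.sum(areas * over))
        if lhs <= rhs + 1e-12:
            return float(r)
    return float(r_upper)


def gaussian_two_class_error_pct():
    """Closed-form one-measurement ML error for N(0,1) vs N(1,1): Phi(-1/2)."""
    from scipy.stats import norm

    return 100.0 * float(norm.cdf(-0.5))
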