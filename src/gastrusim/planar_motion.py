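"""In-plane cell movement: equilibration and oriented intercalation.

Two displacement rules act on every in-plane cell within each tick, in a
fixed number of interleaved sub-iterations (Lloyd's algorithm never being
run to convergence because intercalation keeps perturbing it):

* **Equilibration** moves each cell to the centroid of its pseudo-Voronoi
  region, homogenising density ("Voronoi iteration").
* **Oriented intercalation (OI)** moves each Wnt-PCP-positive cell toward
  the line through each Wnt-PCP-positive near-neighbour along the
  consensus axis, with per-neighbour magnitude |sin(theta)| x step, where
  theta is the angle between the cell->neighbour direction and the cell's
  own axis.  Cells thereby pull into files parallel to the axis: the
  cohort converges perpendicular to the axis and extends along it
  (convergent extension).

OI axes are nematic (axis without head/tail).  Each tick they are
re-computed by consensus: every cell averages its own axis with the
sign-aligned mean of its near-neighbours' axes, marginal-zone pseudo-cells
contributing a fixed reference axis perpendicular to the local ring
tangent, which anchors the global pattern.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import voronoi_mobile_centroids, region_centroid

__all__ = [
    "equilibration_vector",
    "run_equilibration",
    "oi_consensus_update",
    "mz_reference_axis",
    "oi_displacement",
]

_CONSENSUS_TOL_RAD = np.deg2rad(0.5)
_CONSENSUS_MAX_ITER = 200


# ---------------------------------------------------------------------------
# per-cell API


def equilibration_vector(cell, tess) -> np.ndarray:
    """Displacement from the cell centre to its pseudo-VR centroid."""
    region = tess.regions.get(cell.id)
    if region is None:
        warnings.warn(f"cell {cell.id} has no pseudo-Voronoi region", stacklevel=2)
        return np.zeros(2)
    return region_centroid(region) - np.asarray(cell.xy, dtype=float)


def mz_reference_axis(ring, i: int) -> np.ndarray:
    """Unit axis perpendicular to the local MZ tangent at ring point ``i``."""
    pts = np.asarray(getattr(ring, "points", ring), dtype=float)
    n = pts.shape[0]
    chord = pts[(i + 1) % n] - pts[(i - 1) % n]
    axis = np.array([-chord[1], chord[0]])
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        return np.array([1.0, 0.0])
    return axis / nrm


def ring_reference_axes(ring_points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`mz_reference_axis` for all ring points."""
    p = np.asarray(ring_points, dtype=float)
    chord = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
    axes = np.column_stack([-chord[:, 1], chord[:, 0]])
    nrm = np.linalg.norm(axes, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return axes / nrm


def _pair_oi(pts_i, pts_j, axis_i, axis_j, step):
    """OI contribution to the cell at ``pts_i`` from neighbour ``pts_j``."""
    dvec = pts_j - pts_i
    d = np.linalg.norm(dvec)
    if d == 0:
        return np.zeros(2)
    u = dvec / d
    sin_theta = abs(u[0] * axis_i[1] - u[1] * axis_i[0])
    foot = pts_j + np.dot(pts_i - pts_j, axis_j) * axis_j
    direction = foot - pts_i
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        return np.zeros(2)
    return step * sin_theta * direction / nrm


def oi_displacement(cell, tess, step: float) -> np.ndarray:
    """Summed OI displacement of one cell over its Wnt-PCP-positive neighbours.

    For each eligible neighbour the cell moves toward the line through the
    neighbour along the neighbour's axis, with magnitude |sin(theta)| x step
    (zero when the neighbour already lies along the cell's own axis, maximal
    when the cells are side-by-side).  The |sin| makes the rule invariant
    under axis sign flips (nematic symmetry).
    """
    if not cell.wntpcp_positive or cell.oi_blocked or cell.oi_axis is None:
        return np.zeros(2)
    total = np.zeros(2)
    xy = np.asarray(cell.xy, dtype=float)
    for j in tess.near_neighbours(cell.id):
        if j < 0 or j not in tess.cells:
            continue
        other = tess.cells[j]
        if not other.wntpcp_positive or other.oi_blocked or other.oi_axis is None:
            continue
        total += _pair_oi(xy, np.asarray(other.xy, dtype=float), cell.oi_axis, other.oi_axis, step)
    return total


# ---------------------------------------------------------------------------
# vectorized relaxation loop (engine hot path)


def _oi_field(pts, edges, axes, step):
    """Summed OI displacement for every cell, over active edge pairs."""
    out = np.zeros_like(pts)
    if edges.shape[0] == 0:
        return out
    i, j = edges[:, 0], edges[:, 1]
    dvec = pts[j] - pts[i]
    d = np.hypot(dvec[:, 0], dvec[:, 1])
    d[d == 0] = np.inf
    u = dvec / d[:, None]
    ai, aj = axes[i], axes[j]

    def halves(u_dir, a_own, a_nb, src, dst, dst_idx):
        sin_t = np.abs(u_dir[:, 0] * a_own[:, 1] - u_dir[:, 1] * a_own[:, 0])
        rel = pts[dst_idx] - src
        foot = src + np.einsum("ij,ij->i", rel, a_nb)[:, None] * a_nb
        direction = foot - pts[dst_idx]
        nrm = np.hypot(direction[:, 0], direction[:, 1])
        good = nrm > 1e-12
        contrib = np.zeros_like(direction)
        contrib[good] = (
            step * sin_t[good, None] * direction[good] / nrm[good, None]
        )
        np.add.at(out, dst_idx, contrib)

    halves(u, ai, aj, pts[j], None, i)
    halves(-u, aj, ai, pts[i], None, j)
    return out


def run_equilibration(state, n_iter: int | None = None) -> None:
    """Interleaved Lloyd equilibration + OI for one tick, in place.

    Each sub-iteration rebuilds the tessellation, moves every mobile cell
    (epithelium + tethered-EMT tether points, grafted cells excepted) to
    its region centroid, and adds the OI displacement of eligible cells.
    Cells never cross the MZ ring: any point ending outside is pulled back
    inside along the ray to the ring centroid.
    """
    p = state.params
    if n_iter is None:
        n_iter = p.equil_iters_per_tick
    mobile = state.in_plane_cells()
    n_mobile = len(mobile)
    if n_mobile == 0 or n_iter == 0:
        return
    pts = np.array([c.xy for c in mobile], dtype=float)
    immobile = np.fromiter((c.graft for c in mobile), dtype=bool, count=n_mobile)
    active = np.fromiter(
        (
            c.wntpcp_positive and not c.oi_blocked and c.oi_axis is not None and not c.graft
            for c in mobile
        ),
        dtype=bool,
        count=n_mobile,
    )
    axes = np.zeros((n_mobile, 2))
    for k, c in enumerate(mobile):
        if active[k]:
            axes[k] = c.oi_axis
    ring_pts = state.mz_ring.points
    step = p.oi_step_um
    any_oi = bool(active.any())

    substeps = max(1, int(getattr(p, "oi_substeps", 1)))
    for _ in range(n_iter):
        all_pts = np.vstack([pts, ring_pts])
        cents, ok, edges = voronoi_mobile_centroids(all_pts, n_mobile)
        move = ok & ~immobile
        new_pts = np.where(move[:, None], cents, pts)
        if any_oi:
            e = edges[(edges[:, 0] < n_mobile) & (edges[:, 1] < n_mobile)]
            e = e[active[e[:, 0]] & active[e[:, 1]]]
            if e.shape[0]:
                # oi_substeps > 1 applies several small OI updates per
                # tessellation rebuild (geometry re-evaluated, adjacency
                # held), emulating a larger sub-iteration count per tick at
                # a fraction of the tessellation cost
                for _k in range(substeps):
                    new_pts = new_pts + _oi_field(new_pts, e, axes, step)
        pts = new_pts

    # containment: no mobile cell may exit the MZ polygon
    inside = state.mz_ring.contains(pts)
    if not inside.all():
        centre = state.mz_ring.centroid
        for k in np.flatnonzero(~inside):
            lo, hi = 0.0, 1.0
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                cand = centre + mid * (pts[k] - centre)
                if state.mz_ring.contains(cand[None, :])[0]:
                    lo = mid
                else:
                    hi = mid
            pts[k] = centre + 0.98 * lo * (pts[k] - centre)

    for k, c in enumerate(mobile):
        if not immobile[k]:
            c.xy = pts[k]
    state.invalidate_tessellation()


# ---------------------------------------------------------------------------
# consensus orientation


def consensus_axes(
    axes: np.ndarray,
    active: np.ndarray,
    cell_edges: np.ndarray,
    ring_edges: np.ndarray,
    ring_axes: np.ndarray,
    tol: float = _CONSENSUS_TOL_RAD,
    max_iter: int = _CONSENSUS_MAX_ITER,
) -> np.ndarray:
    """Iterate the nematic consensus rule to a stable arrangement.

    ``cell_edges`` are index pairs of active cells; ``ring_edges`` pairs
    (cell_index, ring_index) coupling boundary cells to the fixed MZ
    reference axes.  Each cell's new axis is
    ``normalize(axis + normalize(sum of sign-aligned neighbour axes))``;
    neighbour axes are flipped to positive dot product with the cell's
    current axis before summing (sign flips of any axis leave the dynamics
    unchanged).  Iterates until the largest angular change drops below
    ``tol`` radians or ``max_iter`` sweeps.
    """
    axes = axes.copy()
    n = axes.shape[0]
    for _ in range(max_iter):
        s = np.zeros((n, 2))
        if cell_edges.shape[0]:
            i, j = cell_edges[:, 0], cell_edges[:, 1]
            dots = np.einsum("ij,ij->i", axes[i], axes[j])
            sgn = np.where(dots >= 0, 1.0, -1.0)
            np.add.at(s, i, sgn[:, None] * axes[j])
            np.add.at(s, j, sgn[:, None] * axes[i])
        if ring_edges.shape[0]:
            ci, rk = ring_edges[:, 0], ring_edges[:, 1]
            dots = np.einsum("ij,ij->i", axes[ci], ring_axes[rk])
            sgn = np.where(dots >= 0, 1.0, -1.0)
            np.add.at(s, ci, sgn[:, None] * ring_axes[rk])
        s_norm = np.hypot(s[:, 0], s[:, 1])
        upd = active & (s_norm > 1e-12)
        if not upd.any():
            break
        new = axes.copy()
        blended = axes[upd] + s[upd] / s_norm[upd, None]
        b_norm = np.hypot(blended[:, 0], blended[:, 1])
        keep = b_norm > 1e-12  # antiparallel degeneracy: keep previous axis
        rows = np.flatnonzero(upd)[keep]
        new[rows] = blended[keep] / b_norm[keep, None]
        dcos = np.abs(np.einsum("ij,ij->i", new[active], axes[active]))
        change = np.arccos(np.clip(dcos, 0.0, 1.0))
        axes = new
        if change.size == 0 or change.max() < tol:
            break
    return axes


def oi_consensus_update(state) -> None:
    """Recompute the OI axes of all Wnt-PCP-positive cells by consensus."""
    mobile = state.in_plane_cells()
    n_mobile = len(mobile)
    if n_mobile == 0:
        return
    active = np.fromiter(
        (c.wntpcp_positive and not c.oi_blocked and c.oi_axis is not None for c in mobile),
        dtype=bool,
        count=n_mobile,
    )
    if not active.any():
        return
    axes = np.zeros((n_mobile, 2))
    axes[:, 0] = 1.0
    for k, c in enumerate(mobile):
        if active[k]:
            axes[k] = c.oi_axis
    pts = np.array([c.xy for c in mobile], dtype=float)
    ring_pts = state.mz_ring.points
    all_pts = np.vstack([pts, ring_pts])
    _, _, edges = voronoi_mobile_centroids(all_pts, n_mobile)

    both_cells = (edges[:, 0] < n_mobile) & (edges[:, 1] < n_mobile)
    ce = edges[both_cells]
    ce = ce[active[ce[:, 0]] & active[ce[:, 1]]]
    mixed = edges[(edges[:, 0] < n_mobile) != (edges[:, 1] < n_mobile)]
    if mixed.shape[0]:
        cell_idx = np.where(mixed[:, 0] < n_mobile, mixed[:, 0], mixed[:, 1])
        ring_idx = np.where(mixed[:, 0] < n_mobile, mixed[:, 1], mixed[:, 0]) - n_mobile
        keep = active[cell_idx]
        re = np.column_stack([cell_idx[keep], ring_idx[keep]])
    else:
        re = np.zeros((0, 2), dtype=int)
    ring_axes = ring_reference_axes(ring_pts)

    new_axes = consensus_axes(axes, active, ce, re, ring_axes)
    for k, c in enumerate(mobile):
        if active[k]:
            c.oi_axis = new_axes[k]
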