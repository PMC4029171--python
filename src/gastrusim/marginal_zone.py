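"""The deformable marginal-zone (MZ) boundary ring.

The MZ is an ordered closed ring of non-dividing pseudo-cells that confines
the epiblast.  Once per tick each ring point receives a displacement that
is the sum of three terms: a curvature vector that flattens local bumps, an
outward density push from nearby epiblast cells, and an area-correction
vector that steers the enclosed area toward a slowly growing target, so
that overall epiblast cell density rises gradually even as cells divide.
After displacement the ring is resampled to keep point spacing near its
target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .geometry import mz_curvature, polygon_area
from .mathkit import distance_weights

__all__ = [
    "MarginalZoneRing",
    "target_epiblast_area",
    "mz_displacement",
    "apply_mz_displacement",
    "resample_ring",
]

# hard cap on the area-correction displacement per tick (μm); must exceed
# the curvature pull k_curv/R so the area loop can close on small rings
_MAX_AREA_STEP = 2.0


@dataclass
class MarginalZoneRing:
    """Ordered closed polyline of MZ pseudo-cell positions (CCW, μm)."""

    points: np.ndarray
    spacing_target: float
    prev_target_area: float = 0.0
    initial_area: float = 0.0
    initial_cells_area: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if polygon_area(self.points) < 0:  # enforce CCW orientation
            self.points = self.points[::-1].copy()
        if self.initial_area == 0.0:
            self.initial_area = self.area
        if self.prev_target_area == 0.0:
            self.prev_target_area = self.initial_area

    @property
    def area(self) -> float:
        return abs(polygon_area(self.points))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized point-in-ring test for an (n, 2) array."""
        return MplPath(self.points).contains_points(np.atleast_2d(xy))

    def outward_normals(self) -> np.ndarray:
        """Unit outward normal at every ring point (chord construction)."""
        p = self.points
        chord = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        # rotate CCW tangent by -90 degrees -> outward for a CCW ring
        n = np.column_stack([chord[:, 1], -chord[:, 0]])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms


def target_epiblast_area(ring: MarginalZoneRing, cells_area: float, t: float, p) -> float:
    """Target enclosed epiblast area at time ``t`` (hours).

    The candidate area scales the initial epiblast area by the growth of
    total cell cross-section and shrinks it by a logarithmic density-rise
    factor ``1 - k_area * log10(1 + 9 t / k_t)``; the running maximum makes
    the target non-decreasing.  Updates ``ring.prev_target_area``.
    """
    if cells_area <= 0:
        raise ValueError("cells_area must be positive")
    mz = p.mz
    candidate = (
        (cells_area / ring.initial_cells_area)
        * ring.initial_area
        * (1.0 - mz.k_area * np.log10(1.0 + 9.0 * t / mz.k_t))
    )
    target = max(ring.prev_target_area, candidate)
    ring.prev_target_area = target
    return target


def _density_sums(ring_points: np.ndarray, cell_xy: np.ndarray, p) -> np.ndarray:
    """Kernel-weighted count of epiblast cells near each ring point."""
    mz = p.mz
    out = np.zeros(ring_points.shape[0])
    if cell_xy.shape[0] == 0:
        return out
    tree = cKDTree(cell_xy)
    from .mathkit import KernelParams

    kp = KernelParams(sigma_d=mz.sigma_d, d_max=mz.d_max)
    for i, hits in enumerate(tree.query_ball_point(ring_points, mz.d_max)):
        if hits:
            d = np.linalg.norm(cell_xy[hits] - ring_points[i], axis=1)
            out[i] = float(np.sum(distance_weights(d, kp)))
    return out


def _displacements(state, target_area: float) -> np.ndarray:
    """Per-point MZ displacement vectors for the current tick."""
    ring = state.mz_ring
    p = state.params
    pts = ring.points
    n = pts.shape[0]
    cell_xy = np.array(
        [c.xy for c in state.cells if c.kind == "epithelium" or (c.kind == "emt" and c.tethered)],
        dtype=float,
    ).reshape(-1, 2)

    nu_out = ring.outward_normals()
    dens = _density_sums(pts, cell_xy, p)

    # area-correction: uniform normal displacement delta changes the area by
    # ~perimeter * delta, so a proportional controller with unit gain closes
    # the loop in one step when unclamped
    area_err = target_area - ring.area
    f = np.clip(p.mz.area_gain * area_err / ring.perimeter, -_MAX_AREA_STEP, _MAX_AREA_STEP)

    disp = np.empty_like(pts)
    for i in range(n):
        kappa, nu_local = mz_curvature(ring, i)
        v = p.mz.k_curv * abs(kappa) * nu_local
        v = v + p.mz.k_dens * dens[i] * nu_out[i]
        v = v + f * nu_out[i]
        disp[i] = v
    return disp


def mz_displacement(state, i: int) -> np.ndarray:
    """Displacement vector v_MZ = v_curv + v_dens + v_area for ring point ``i``.

    Uses the ring's current target area (``prev_target_area``); the engine
    refreshes the target via :func:`target_epiblast_area` before displacing.
    """
    return _displacements(state, state.mz_ring.prev_target_area)[i]


def apply_mz_displacement(state, target_area: float | None = None) -> None:
    """Displace every ring point once (called at the beginning of a tick)."""
    ring = state.mz_ring
    if target_area is None:
        target_area = ring.prev_target_area
    ring.points = ring.points + _displacements(state, target_area)


def resample_ring(ring: MarginalZoneRing) -> MarginalZoneRing:
    """Insert/remove ring points so spacing returns toward its target.

    Segments longer than 1.5x the target spacing get a midpoint inserted
    (new points lie on existing segments, preserving shape); points closer
    than half the target to their predecessor are dropped.  Iterates until
    all spacings lie within [0.5, 1.5] x target.
    """
    s = ring.spacing_target
    pts = ring.points
    for _ in range(10):
        nxt = np.roll(pts, -1, axis=0)
        seg = np.linalg.norm(nxt - pts, axis=1)
        if np.all((seg >= 0.5 * s) & (seg <= 1.5 * s)):
            break
        out = []
        skip = False
        n = pts.shape[0]
        for i in range(n):
            if skip:
                skip = False
                continue
            out.append(pts[i])
            if seg[i] > 1.5 * s:
                out.append(0.5 * (pts[i] + nxt[i]))
            elif seg[i] < 0.5 * s and len(out) > 1:
                # drop the next point by merging the short segment
                skip = True
        pts = np.asarray(out)
        if pts.shape[0] < 8:
            raise ValueError("ring would drop below 8 points")
    if pts.shape[0] < 8:
        raise ValueError("ring would drop below 8 points")
    ring.points = pts
    return ring
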