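"""Planar neighbour structure of the epithelium.

Cells in the epiblast plane are point generators of an approximate Voronoi
tessellation ("pseudo-Voronoi regions"): straight-edged bisector polygons
that ignore radius differences.  The tessellation supplies (i) the
near-neighbour (abutting) relation used by all juxtacrine interactions,
(ii) region centroids for Lloyd-style equilibration, and, for the marginal
zone ring, (iii) a discrete curvature estimator.

Marginal-zone pseudo-cells participate as boundary generators so that
interior cell regions are finite, but receive no region of their own.
In a :class:`Tessellation`, MZ generators are identified by the negative
ids ``-1 - k`` for ring point ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

__all__ = [
    "Tessellation",
    "build_tessellation",
    "region_centroid",
    "mz_curvature",
    "polygon_area",
]


# ---------------------------------------------------------------------------
# polygon primitives


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a polygon (positive for CCW orientation)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def region_centroid(region: np.ndarray) -> np.ndarray:
    """Exact area-weighted centroid of a polygon given as an (n, 2) array."""
    v = np.asarray(region, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12:
        raise ValueError("zero-area polygon has no centroid")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# fast Voronoi helpers (shared by the public API and the relaxation loop)


def _deduplicate(points: np.ndarray, rng_jitter: float = 1e-6) -> np.ndarray:
    """Jitter exactly coincident generators apart (qhull rejects them)."""
    _, inverse, counts = np.unique(
        points.round(decimals=9), axis=0, return_inverse=True, return_counts=True
    )
    if counts.max() <= 1:
        return points
    warnings.warn("coincident generators jittered by 1e-6 um", stacklevel=3)
    out = points.copy()
    dup = np.flatnonzero(counts[inverse] > 1)
    # deterministic jitter: spread duplicates on a tiny circle
    ang = 2.0 * np.pi * (np.arange(dup.size) + 0.5) / max(dup.size, 1)
    out[dup, 0] += rng_jitter * np.cos(ang)
    out[dup, 1] += rng_jitter * np.sin(ang)
    return out


def voronoi_mobile_centroids(
    all_points: np.ndarray, n_mobile: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Voronoi pass over ``all_points`` (mobile generators first).

    Returns ``(centroids, ok, edges)`` where ``centroids`` holds the region
    centroid for each of the first ``n_mobile`` generators (the generator's
    own position where the region is unbounded or degenerate, flagged False
    in ``ok``), and ``edges`` is the (m, 2) array of generator index pairs
    sharing a ridge (the near-neighbour relation).

    Centroids are accumulated ridge-wise: every Voronoi region is convex
    and contains its generator, so the triangles (generator, ridge vertex
    pair) partition it exactly; this avoids any per-region Python loop.
    """
    pts = np.asarray(all_points, dtype=float)
    try:
        vor = Voronoi(pts)
    except Exception:
        pts = _deduplicate(pts)
        vor = Voronoi(pts)
    centroids = pts[:n_mobile].copy()

    rp = vor.ridge_points
    rv = np.asarray(vor.ridge_vertices, dtype=np.intp)
    finite = (rv[:, 0] >= 0) & (rv[:, 1] >= 0)
    n = pts.shape[0]
    area = np.zeros(n)
    cacc = np.zeros((n, 2))
    unbounded = np.zeros(n, dtype=bool)
    inf_pts = rp[~finite].ravel()
    unbounded[inf_pts] = True

    rp_f = rp[finite]
    v1 = vor.vertices[rv[finite, 0]]
    v2 = vor.vertices[rv[finite, 1]]
    for side in (0, 1):
        g = rp_f[:, side]
        p = pts[g]
        a = 0.5 * np.abs(
            (v1[:, 0] - p[:, 0]) * (v2[:, 1] - p[:, 1])
            - (v2[:, 0] - p[:, 0]) * (v1[:, 1] - p[:, 1])
        )
        c = (p + v1 + v2) / 3.0
        np.add.at(area, g, a)
        np.add.at(cacc, g, a[:, None] * c)

    ok = (~unbounded[:n_mobile]) & (area[:n_mobile] > 1e-12)
    sel = np.flatnonzero(ok)
    centroids[sel] = cacc[sel] / area[sel, None]
    return centroids, ok, rp


# ---------------------------------------------------------------------------
# public tessellation object


@dataclass
class Tessellation:
    """Pseudo-Voronoi tessellation of the in-plane cells.

    ``points`` maps generator id -> position; cell ids are the model cell
    ids and MZ ring points carry ids ``-1 - k``.  ``regions`` maps cell id
    -> (n, 2) polygon vertex array (MZ generators own no region).
    ``cells`` maps cell id -> Cell for in-plane cells, ``offplane`` holds
    untethered EMT cells that count only as distance-weighted effectors.
    """

    points: dict[int, np.ndarray]
    regions: dict[int, np.ndarray]
    adjacency: dict[int, set[int]]
    cells: dict[int, object]
    offplane: dict[int, object] = field(default_factory=dict)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.points[i] - self.points[j]))

    def near_neighbours(self, i: int) -> set[int]:
        return self.adjacency.get(i, set())


def build_tessellation(state) -> Tessellation:
    """Build the pseudo-Voronoi tessellation for the current embryo state.

    Generators are the in-plane positions of epithelial cells, the tether
    points of tethered EMT cells, and the MZ ring pseudo-cells.  Regions of
    cells are clipped to the ring polygon; adjacency pairs are generators
    sharing a ridge.
    """
    in_plane = [c for c in state.cells if c.kind == "epithelium" or (c.kind == "emt" and c.tethered)]
    if len(in_plane) + len(state.mz_ring.points) < 3:
        raise ValueError("need at least 3 in-plane generators")
    ids = [c.id for c in in_plane]
    pts = np.array([c.xy for c in in_plane], dtype=float)
    ring = np.asarray(state.mz_ring.points, dtype=float)
    ring_ids = [-1 - k for k in range(ring.shape[0])]
    all_ids = ids + ring_ids
    all_pts = np.vstack([pts, ring]) if len(in_plane) else ring

    dedup = _deduplicate(all_pts)
    vor = Voronoi(dedup)
    ring_poly = Polygon(ring)

    regions: dict[int, np.ndarray] = {}
    for k, cid in enumerate(ids):
        reg = vor.regions[vor.point_region[k]]
        if len(reg) < 3 or -1 in reg:
            continue
        poly = Polygon(vor.vertices[reg])
        clipped = poly.intersection(ring_poly)
        if clipped.is_empty or clipped.geom_type != "Polygon":
            regions[cid] = np.asarray(poly.exterior.coords[:-1])
        else:
            regions[cid] = np.asarray(clipped.exterior.coords[:-1])

    adjacency: dict[int, set[int]] = {i: set() for i in all_ids}
    for a, b in vor.ridge_points:
        ia, ib = all_ids[a], all_ids[b]
        adjacency[ia].add(ib)
        adjacency[ib].add(ia)

    points = {all_ids[k]: dedup[k] for k in range(len(all_ids))}
    cells = {c.id: c for c in in_plane}
    offplane = {
        c.id: c for c in state.cells if c.kind == "emt" and not c.tethered
    }
    return Tessellation(
        points=points, regions=regions, adjacency=adjacency, cells=cells, offplane=offplane
    )


# ---------------------------------------------------------------------------
# marginal-zone curvature


def mz_curvature(ring, i: int) -> tuple[float, np.ndarray]:
    """Discrete signed curvature at ring point ``i`` with its local normal.

    Estimated from the circumscribed circle of points (i-1, i, i+1) of the
    closed polyline.  The sign is positive where the ring is locally convex
    (curvature centre on the epiblast side); the returned unit normal points
    toward the curvature centre.  A collinear triple has zero curvature and
    the normal falls back to the inward disc normal.
    """
    pts = np.asarray(getattr(ring, "points", ring), dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("ring needs at least 3 points")
    a, b, c = pts[(i - 1) % n], pts[i % n], pts[(i + 1) % n]
    centroid = pts.mean(axis=0)

    d1, d2 = b - a, c - b
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    chord = c - a
    chord_norm = np.linalg.norm(chord)
    if abs(cross) < 1e-12 * max(chord_norm, 1.0) ** 2:
        inward = centroid - b
        nrm = np.linalg.norm(inward)
        normal = inward / nrm if nrm > 0 else np.array([0.0, 0.0])
        return 0.0, normal

    # circumcentre of (a, b, c)
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    centre = np.array([ux, uy])
    r = np.linalg.norm(centre - b)
    kappa = 1.0 / r
    to_centre = centre - b
    normal = to_centre / np.linalg.norm(to_centre)
    # convex iff the curvature centre lies on the same side as the ring interior
    sign = 1.0 if np.dot(to_centre, centroid - b) > 0 else -1.0
    return sign * kappa, normal
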