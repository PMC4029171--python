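"""Quantitative phenotypes of a simulation.

Morphometrics of the forming primitive streak (principal-component length,
width and orientation of the Nodal-positive cohort), a rotational
"Polonaise" index summarising the bilateral whorl movements of pre-streak
trails, trajectory straightness, and regional ingression statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

__all__ = [
    "StreakMorphometrics",
    "streak_morphometrics",
    "streak_cell_count",
    "PolonaiseIndex",
    "polonaise_index",
    "straightness",
    "ingression_stats",
]


@dataclass(frozen=True)
class StreakMorphometrics:
    n_cells: int
    length: float  # μm, 4 sqrt(lambda_1): ~95% extent for Gaussian spread
    width: float  # μm, 4 sqrt(lambda_2)
    aspect_ratio: float
    axis_angle: float  # radians in [0, pi), first principal axis
    midline_offset: float  # μm, |mean x|
    degenerate: bool = False


def _streak_positions(state) -> np.ndarray:
    return np.array(
        [
            c.xy
            for c in state.cells
            if c.nodal_positive and (c.kind == "epithelium" or (c.kind == "emt" and c.tethered))
        ],
        dtype=float,
    ).reshape(-1, 2)


def streak_morphometrics(state_or_xy) -> StreakMorphometrics:
    """PCA morphometrics of the Nodal-positive in-plane cohort.

    Accepts an embryo state or an (n, 2) position array.  Length and width
    are 4 sqrt(eigenvalue) of the positional covariance (any fixed multiple
    works, as only ratios and trends are interpreted).
    """
    xy = (
        np.asarray(state_or_xy, dtype=float)
        if isinstance(state_or_xy, np.ndarray)
        else _streak_positions(state_or_xy)
    )
    n = xy.shape[0]
    if n < 3:
        return StreakMorphometrics(n, np.nan, np.nan, np.nan, np.nan, np.nan, True)
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / n
    evals, evecs = np.linalg.eigh(cov)
    lam1, lam2 = float(evals[1]), float(evals[0])
    length = 4.0 * np.sqrt(max(lam1, 0.0))
    width = 4.0 * np.sqrt(max(lam2, 0.0))
    v1 = evecs[:, 1]
    angle = float(np.arctan2(v1[1], v1[0]) % np.pi)
    offset = float(abs(xy[:, 0].mean()))
    degenerate = width < 1e-9
    ar = length / width if width > 1e-9 else np.inf
    return StreakMorphometrics(n, length, width, ar, angle, offset, degenerate)


def streak_cell_count(state) -> int:
    """Cells in the streak: the largest connected Nodal-positive cluster.

    Nodal-positive in-plane cells are linked by near-neighbour adjacency
    and the size of the largest connected component is returned.  This
    counts the coherent streak structure rather than every
    Nodal-positive cell — stray positives and fragments left behind by
    heavy ingression do not inflate a "diminutive" streak.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    cells = [
        c
        for c in state.cells
        if c.nodal_positive and (c.kind == "epithelium" or (c.kind == "emt" and c.tethered))
    ]
    n = len(cells)
    if n == 0:
        return 0
    tess = state.tessellation()
    index = {c.id: k for k, c in enumerate(cells)}
    rows, cols = [], []
    for c in cells:
        for j in tess.near_neighbours(c.id):
            if j in index:
                rows.append(index[c.id])
                cols.append(index[j])
    if not rows:
        return 1
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return int(np.bincount(labels).max())


@dataclass(frozen=True)
class PolonaiseIndex:
    """Mean |net angular sweep| about the disc centre, per bilateral half.

    In the Polonaise pattern the two halves rotate with opposite sign
    (mirror-image whorls), so ``left_signed`` and ``right_signed`` should
    have opposite signs in a normal run.
    """

    left_abs: float
    right_abs: float
    left_signed: float
    right_signed: float
    n_left: int
    n_right: int

    @property
    def mean_abs(self) -> float:
        return 0.5 * (self.left_abs + self.right_abs)

    @property
    def opposite_signs(self) -> bool:
        return self.left_signed * self.right_signed < 0


def _net_sweep(xy: np.ndarray, centre: np.ndarray) -> float:
    """Sum of signed angular increments of a trail about ``centre``."""
    rel = xy - centre
    phi = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return float(phi[-1] - phi[0])


def polonaise_index(
    log,
    window: tuple[int, int],
    centre=(0.0, 0.0),
    min_radius: float = 0.0,
    exclude_intercalating: bool = True,
) -> PolonaiseIndex:
    """Rotational index of cell trails in a tick window.

    For each cell alive throughout part of the window, the net signed
    angular sweep of its trail about the disc centre is computed; trails
    are split into left (mean x < 0) and right (mean x > 0) halves.  The
    Polonaise pattern is a property of the epiblast *around* the
    streak-forming domain, so cells that are Wnt-PCP-positive during the
    window (the actively intercalating cohort) are excluded by default.
    Trails shorter than 2 points, or with mean radius below
    ``min_radius``, are skipped.
    """
    centre = np.asarray(centre, dtype=float)
    trails = log.trails(window=window)
    excluded: set[int] = set()
    if exclude_intercalating:
        for snap in log.snapshots:
            if window[0] <= snap["tick"] <= window[1]:
                excluded.update(
                    int(c) for c in snap["cell_id"][np.asarray(snap["wntpcp"], bool)]
                )
    sweeps: dict[str, list[float]] = {"left": [], "right": []}
    n_used = 0
    for cid, arr in trails.items():
        if cid in excluded or arr.shape[0] < 2:
            continue
        xy = arr[:, 1:3]
        if np.linalg.norm(xy.mean(axis=0) - centre) < min_radius:
            continue
        side = "right" if xy[:, 0].mean() > centre[0] else "left"
        sweeps[side].append(_net_sweep(xy, centre))
        n_used += 1
    if n_used < 10:
        raise ValueError("need at least 10 usable trails in the window")
    left = np.asarray(sweeps["left"])
    right = np.asarray(sweeps["right"])
    return PolonaiseIndex(
        left_abs=float(np.mean(np.abs(left))) if left.size else 0.0,
        right_abs=float(np.mean(np.abs(right))) if right.size else 0.0,
        left_signed=float(np.mean(left)) if left.size else 0.0,
        right_signed=float(np.mean(right)) if right.size else 0.0,
        n_left=int(left.size),
        n_right=int(right.size),
    )


def straightness(trail: np.ndarray) -> float:
    """|net displacement| / path length of a trail; 1.0 for zero path."""
    xy = np.asarray(trail, dtype=float)
    if xy.shape[1] == 3:  # (tick, x, y) rows
        xy = xy[:, 1:3]
    if xy.shape[0] < 2:
        raise ValueError("trail needs at least 2 points")
    seg = np.diff(xy, axis=0)
    path = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    if path == 0.0:
        return 1.0
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    return net / path


def _streak_region_for_tick(snap, dilation: float):
    """Convex hull of the Nodal-positive in-plane cohort, dilated."""
    mask = snap["nodal"] & (
        (snap["kind"] == "epithelium") | ((snap["kind"] == "emt") & snap["tethered"])
    )
    pts = np.column_stack([snap["x"][mask], snap["y"][mask]])
    if pts.shape[0] < 3:
        return None
    return MultiPoint(pts.tolist()).convex_hull.buffer(dilation)


def ingression_stats(
    log,
    region="streak",
    event: str = "untether",
    dilation: Optional[float] = None,
    cell_diameter: float = 10.0,
) -> pd.DataFrame:
    """Per-tick counts of completed ingressions inside/outside a region.

    ``region="streak"`` uses, for each tick, the convex hull of the
    Nodal-positive in-plane cohort dilated by one cell diameter; any
    shapely geometry can be passed instead.  Returns a tidy frame with
    per-tick in/out counts and cumulative fractions.
    """
    if dilation is None:
        dilation = cell_diameter
    events = [e for e in log.events if e["event"] == event]
    snaps = {snap["tick"]: snap for snap in log.snapshots}
    ticks = sorted(snaps)
    rows = []
    cum_in = cum_out = 0
    events_by_tick: dict[int, list] = {}
    for e in events:
        events_by_tick.setdefault(e["tick"], []).append(e)
    for t in ticks:
        snap = snaps[t]
        if region == "streak":
            geom = _streak_region_for_tick(snap, dilation)
        else:
            geom = region
        n_in = n_out = 0
        pos = {int(cid): (x, y) for cid, x, y in zip(snap["cell_id"], snap["x"], snap["y"])}
        for e in events_by_tick.get(t, []):
            xy = pos.get(e["cell_id"])
            if xy is None or geom is None:
                n_out += 1
                continue
            if geom.contains(Point(xy)):
                n_in += 1
            else:
                n_out += 1
        cum_in += n_in
        cum_out += n_out
        total = cum_in + cum_out
        rows.append(
            {
                "tick": t,
                "n_in": n_in,
                "n_out": n_out,
                "cum_in": cum_in,
                "cum_out": cum_out,
                "frac_in": cum_in / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
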