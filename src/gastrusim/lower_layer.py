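"""Schematic hypoblast/endoblast layer.

The lower layer contains no model cells.  It is a pair of animated
polygons: the hypoblast initially covers the whole embryonic disc and
secretes the Nodal antagonist Cerberus, so epiblast positions above it are
Nodal-refractory.  Partway through a run the endoblast appears at the
posterior margin and sweeps anteriorly as a band, displacing the hypoblast
and disinhibiting Nodal in the posterior epiblast — the trigger for
primitive-streak formation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = ["LowerLayer", "make_lower_layer", "hypoblast_covers", "advance_lower_layer"]


@dataclass(frozen=True)
class LowerLayer:
    """State of the schematic lower layer.

    ``front_y`` is the anterior extent (μm) of the endoblast band; positions
    with y <= front_y inside the disc are endoblast (Nodal-disinhibited).
    ``front_y = -inf`` means the endoblast has not yet appeared.
    """

    disc_radius: float
    front_y: float = -np.inf

    @property
    def hypoblast_polygon(self) -> Polygon:
        disc = Point(0.0, 0.0).buffer(self.disc_radius, quad_segs=90)
        if not np.isfinite(self.front_y):
            return disc
        return disc.difference(self._posterior_halfplane())

    @property
    def endoblast_polygon(self) -> Polygon:
        disc = Point(0.0, 0.0).buffer(self.disc_radius, quad_segs=90)
        if not np.isfinite(self.front_y):
            return Polygon()
        return disc.intersection(self._posterior_halfplane())

    def _posterior_halfplane(self) -> Polygon:
        r = self.disc_radius * 1.01
        return Polygon(
            [(-r, -r), (r, -r), (r, self.front_y), (-r, self.front_y)]
        )


def make_lower_layer(disc_radius: float) -> LowerLayer:
    """Initial lower layer: hypoblast covering the full disc, no endoblast."""
    return LowerLayer(disc_radius=disc_radius)


def hypoblast_covers(lower: LowerLayer, xy) -> bool:
    """True iff ``xy`` lies under hypoblast (and hence is Nodal-inhibited).

    Positions outside the embryonic disc, or inside the endoblast band,
    are not covered.
    """
    x, y = float(xy[0]), float(xy[1])
    if x * x + y * y > lower.disc_radius**2:
        return False
    return y > lower.front_y


def hypoblast_covers_many(lower: LowerLayer, xy: np.ndarray) -> np.ndarray:
    """Vectorized :func:`hypoblast_covers` over an (n, 2) position array."""
    xy = np.asarray(xy, dtype=float)
    inside = np.einsum("ij,ij->i", xy, xy) <= lower.disc_radius**2
    return inside & (xy[:, 1] > lower.front_y)


def advance_lower_layer(lower: LowerLayer, tick: int, p) -> LowerLayer:
    """Advance the endoblast front according to the tick schedule.

    Before ``p.endoblast_start_tick`` the layer is unchanged.  Afterwards
    the front starts at the posterior margin and moves anteriorly at
    ``p.endoblast_front_speed_frac`` of the disc diameter per tick,
    saturating at ``p.endoblast_stop_y_frac`` of the disc radius.
    """
    if tick < p.endoblast_start_tick:
        return lower
    speed = p.endoblast_front_speed_frac * 2.0 * lower.disc_radius
    k = tick - p.endoblast_start_tick
    stop_y = p.endoblast_stop_y_frac * lower.disc_radius
    front = min(-lower.disc_radius + k * speed, stop_y)
    if front <= lower.front_y:
        return lower
    return replace(lower, front_y=front)
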