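"""Cell growth and symmetric planar division with state inheritance.

Epithelial cells cycle independently with a mean cycle time of 6 hr
(per-cell lengths drawn from a normal truncated at +-3 SD, CV 10%).  A
division is symmetric: daughters are placed half a radius to either side
of the parent along a uniformly random planar axis, start at half the
parental volume (radius x 2^(-1/3)) and regrow linearly to full size over
one hour.  Daughters inherit the parent's Nodal/Wnt-PCP states and
intercalation axis.  EMT, meso and MZ cells do not divide.
"""

from __future__ import annotations

import numpy as np

from .model_state import Cell, draw_cycle_lengths

__all__ = ["advance_cycle", "divide", "regrow_radius"]

HALF_VOLUME_RADIUS_FACTOR = 2.0 ** (-1.0 / 3.0)


def advance_cycle(cell: Cell, dt: float, rng=None) -> bool:
    """Advance the cycle clock by ``dt`` hours; True when division is due.

    Only epithelial cells cycle; for any other kind this is a no-op.
    """
    if cell.kind != "epithelium":
        return False
    cell.cycle_age += dt
    return cell.cycle_age >= cell.cycle_length


def divide(cell: Cell, rng: np.random.Generator, params, id_pair: tuple[int, int]) -> tuple[Cell, Cell]:
    """Split ``cell`` into two daughters along a random planar axis."""
    theta = rng.random() * np.pi
    axis = np.array([np.cos(theta), np.sin(theta)])
    offset = 0.5 * cell.radius * axis
    lengths = draw_cycle_lengths(params, rng, 2)
    birth_radius = params.cell_radius_um * HALF_VOLUME_RADIUS_FACTOR

    daughters = []
    for k, sign in enumerate((1.0, -1.0)):
        d = Cell(
            id=id_pair[k],
            xy=np.asarray(cell.xy, dtype=float) + sign * offset,
            z=0.0,
            radius=birth_radius,
            kind="epithelium",
            nodal_positive=cell.nodal_positive,
            wntpcp_positive=cell.wntpcp_positive,
            oi_axis=None if cell.oi_axis is None else cell.oi_axis.copy(),
            oi_blocked=cell.oi_blocked,
            cycle_age=0.0,
            cycle_length=float(lengths[k]),
            parent_id=cell.id,
        )
        daughters.append(d)
    return daughters[0], daughters[1]


def regrow_radius(cell: Cell, dt: float, params) -> None:
    """Linear radius regrowth after division, capped at full size."""
    full = params.cell_radius_um
    if cell.radius >= full:
        return
    rate = (full - full * HALF_VOLUME_RADIUS_FACTOR) / params.regrowth_hr
    cell.radius = min(full, cell.radius + rate * dt)
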