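"""EMT initiation, tethered bobbing, reversion, untethering, mesenchyme.

An epithelial cell stochastically initiates EMT at a rate that rises
steeply (logistic in N_eff) with the number of Nodal-positive effector
neighbours — the community effect.  While the EMT cell remains tethered it
bobs up and down below the plane: the deeper it is, the stronger the bias
to keep descending.  Tethered cells whose body is still partly above the
basement membrane (z >= -2r) may revert to epithelium unless the local
Nodal effect is at/above threshold; once fully below the BM they may
untether, after which descent is one-way and ends in terminal mesenchyme
(which loses all signalling positivity).

Kind transitions form the DAG
``epithelium -> t-emt -> {epithelium, u-emt}; u-emt -> meso``.
"""

from __future__ import annotations


from .mathkit import logistic_probability, per_tick_probability
from .signalling import nodal_activity

__all__ = [
    "emt_conversion_probability",
    "direction_change_probability",
    "reversion_probability",
    "untether_probability",
    "vertical_step",
]


def emt_conversion_probability(cell, state, tess=None, level: float | None = None) -> float:
    """Per-hour hazard of epithelium -> tethered-EMT conversion.

    The logistic argument is the cell's Nodal N_eff (self + near-neighbour
    + distance-weighted local terms, hypoblast-gated coefficients).
    """
    if cell.kind != "epithelium":
        raise ValueError("EMT conversion applies to epithelial cells only")
    if level is None:
        level = nodal_activity(cell, state, tess).level
    return logistic_probability(level, state.params.emt.logistic)


def direction_change_probability(z: float, direction: str, p) -> float:
    """Per-hour hazard that a tethered EMT cell flips vertical direction.

    Ascending cells become ever more likely to turn back down as they
    descend (0.8 -> 0.0 with rising z); descending cells turn upward with
    at most 0.4/hr near the plane and essentially never at depth.
    """
    if direction == "ascending":
        return logistic_probability(z, p.dirchange_up)
    if direction == "descending":
        return logistic_probability(z, p.dirchange_down)
    raise ValueError(f"unknown direction {direction!r}")


def reversion_probability(cell, state, tess=None, level: float | None = None) -> float:
    """Per-hour hazard of tethered-EMT -> epithelium reversion.

    Prohibited (0.0) for untethered cells, for cells fully below the BM,
    for grafted cells, and when the local Nodal effect is at or above the
    reversion threshold; otherwise a logistic in depth (0.30 -> 0.90).
    """
    if cell.kind != "emt":
        raise ValueError("reversion applies to EMT cells only")
    p = state.params
    if not cell.tethered or cell.graft:
        return 0.0
    if cell.z < p.bm_depth_um:
        return 0.0
    if level is None:
        level = nodal_activity(cell, state, tess).level
    if level >= p.nodal_reversion_threshold:
        return 0.0
    return logistic_probability(cell.z, p.reversion)


def untether_probability(z: float, p) -> float:
    """Per-hour hazard of tether release, increasing with depth.

    Zero (prohibited) while any part of the cell body is above the BM
    (z >= -2r).  Below the BM the hazard follows the printed logistic
    parameter table (midpoint -12.5 μm, range 0 -> 0.999) with the depth
    axis mirrored about the midpoint so that the probability grows as the
    cell descends, as the tether mechanics require.
    """
    if z >= p.bm_depth_um:
        return 0.0
    lp = p.untether
    return logistic_probability(2.0 * lp.m - z, lp)


def vertical_step(cell, state, log=None, level: float | None = None) -> None:
    """One tick of vertical EMT dynamics for a single EMT cell.

    Sub-steps in fixed order: (1) tethered cells may flip direction,
    (2) move z by the vertical speed (the plane is a ceiling), (3) tethered
    cells may revert to epithelium, (4) tethered cells fully below the BM
    may untether, (5) untethered cells keep descending and become meso at
    the terminal depth, losing Nodal/Wnt-PCP positivity.  Grafted cells are
    static Nodal sources and are skipped.
    """
    if cell.kind != "emt":
        raise ValueError("vertical_step applies to EMT cells only")
    if cell.graft:
        return
    p = state.params
    dt = p.dt_hr
    rng = state.rng
    tick = state.tick

    if cell.tethered:
        p_flip = per_tick_probability(
            direction_change_probability(cell.z, cell.vertical_direction, p), dt
        )
        if rng.random() < p_flip:
            cell.vertical_direction = (
                "ascending" if cell.vertical_direction == "descending" else "descending"
            )

    dz = p.vertical_speed_um_per_tick
    if cell.tethered:
        cell.z += dz if cell.vertical_direction == "ascending" else -dz
        cell.z = min(cell.z, 0.0)
    else:
        cell.z -= dz

    if cell.tethered:
        p_rev = per_tick_probability(reversion_probability(cell, state, level=level), dt)
        if p_rev > 0.0 and rng.random() < p_rev:
            cell.kind = "epithelium"
            cell.z = 0.0
            cell.tethered = False
            cell.vertical_direction = None
            if log is not None:
                log.record_event(tick, cell.id, "reversion")
            return

    if cell.tethered and cell.z < p.bm_depth_um:
        p_unt = per_tick_probability(untether_probability(cell.z, p), dt)
        if rng.random() < p_unt:
            cell.tethered = False
            cell.vertical_direction = "descending"
            if log is not None:
                log.record_event(tick, cell.id, "untether")

    if not cell.tethered and cell.z <= p.meso_depth_um:
        cell.kind = "meso"
        cell.nodal_positive = False
        cell.wntpcp_positive = False
        cell.oi_axis = None
        cell.vertical_direction = None
        if log is not None:
            log.record_event(tick, cell.id, "meso")
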