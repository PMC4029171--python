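"""The hierarchical tick scheduler.

One tick is 10 min of biological time.  Each tick executes a fixed phase
order: (1) advance the lower layer, (2) displace and resample the MZ ring
(once, at the beginning of the tick), (3) rebuild the neighbour structure,
(4) synchronous stochastic state conversions — Nodal, then Wnt-PCP, then
EMT initiation, all evaluated against the start-of-tick state and applied
together, (5) vertical EMT sub-steps, (6) cell cycling and divisions,
(7) the interleaved equilibration/OI sub-iterations, (8) the OI consensus
update, and (9) logging.  All stochastic draws consume a single seeded RNG
stream in cell-id order, so a run is deterministic given (scenario, seed).
"""

from __future__ import annotations

import numpy as np

from . import cell_cycle, emt_dynamics, planar_motion, signalling
from .geometry import voronoi_mobile_centroids
from .lower_layer import advance_lower_layer
from .marginal_zone import apply_mz_displacement, resample_ring, target_epiblast_area
from .mathkit import logistic_probability, per_tick_probabilities
from .model_state import EmbryoState, SimulationLog, initialize_embryo

__all__ = ["TICK_PHASES", "step", "run"]

#: Fixed per-tick phase order.
TICK_PHASES = (
    "advance_lower_layer",
    "marginal_zone",
    "tessellation",
    "state_conversions",
    "vertical_emt",
    "cell_cycle",
    "equilibration_oi",
    "oi_consensus",
    "logging",
)


def _conversion_phase(state: EmbryoState, log: SimulationLog | None) -> None:
    """Synchronous Nodal -> Wnt-PCP -> EMT-initiation conversions.

    All N_eff fields and hazards are computed from the start-of-tick state
    and the resulting flips applied together, so the outcome does not
    depend on cell iteration order.
    """
    p = state.params
    dt = p.dt_hr
    mobile = state.in_plane_cells()
    n_in = len(mobile)
    if n_in == 0:
        return
    pts = np.array([c.xy for c in mobile], dtype=float)
    off = [c for c in state.cells if c.kind == "emt" and not c.tethered]
    pts_off = np.array([c.xy for c in off], dtype=float).reshape(-1, 2)
    nodal = np.fromiter(
        (c.nodal_positive for c in mobile + off), dtype=float, count=n_in + len(off)
    )
    wnt = np.fromiter(
        (c.wntpcp_positive for c in mobile + off), dtype=float, count=n_in + len(off)
    )
    ring_pts = state.mz_ring.points
    _, _, edges = voronoi_mobile_centroids(np.vstack([pts, ring_pts]), n_in)
    cell_edges = edges[(edges[:, 0] < n_in) & (edges[:, 1] < n_in)]

    fields = signalling.compute_fields(
        pts, pts_off, nodal, wnt, cell_edges, state.lower, p
    )
    state._fields_cache = (mobile, fields)

    is_epi = np.fromiter((c.kind == "epithelium" for c in mobile), dtype=bool, count=n_in)

    # Nodal conversion (Nodal-negative epithelium)
    cand = is_epi & (nodal[:n_in] == 0.0)
    p_hr = np.array(
        [logistic_probability(x, p.nodal_conv.logistic) for x in fields["nodal_conv"]]
    )
    draw = state.rng.random(n_in)
    nodal_on = cand & (draw < per_tick_probabilities(p_hr, dt))

    # Wnt-PCP conversion (Nodal-positive, Wnt-PCP-negative epithelium;
    # evaluated on start-of-tick Nodal states)
    cand = is_epi & (nodal[:n_in] == 1.0) & (wnt[:n_in] == 0.0)
    p_hr = np.array(
        [logistic_probability(x, p.wntpcp_conv.logistic) for x in fields["wnt_conv"]]
    )
    draw = state.rng.random(n_in)
    wnt_on = cand & (draw < per_tick_probabilities(p_hr, dt))

    # EMT initiation (epithelium)
    p_hr = np.array(
        [logistic_probability(x, p.emt.logistic) for x in fields["nodal_level"]]
    )
    draw = state.rng.random(n_in)
    emt_on = is_epi & (draw < per_tick_probabilities(p_hr, dt))

    tick = state.tick
    for k in np.flatnonzero(nodal_on):
        mobile[k].nodal_positive = True
        if log is not None:
            log.record_event(tick, mobile[k].id, "nodal_on")
    for k in np.flatnonzero(wnt_on):
        mobile[k].wntpcp_positive = True
        if log is not None:
            log.record_event(tick, mobile[k].id, "wntpcp_on")
    for k in np.flatnonzero(emt_on):
        c = mobile[k]
        c.kind = "emt"
        c.tethered = True
        c.vertical_direction = "descending"
        c.z = 0.0
        if log is not None:
            log.record_event(tick, c.id, "emt_start")

    # give freshly Wnt-PCP-positive cells an initial axis from their
    # neighbours' consensus (or the local outward radial as a fallback)
    fresh = np.flatnonzero(wnt_on)
    if fresh.size:
        adj: dict[int, list[int]] = {}
        for a, b in cell_edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        for k in fresh:
            c = mobile[k]
            s = np.zeros(2)
            ref = None
            for j in adj.get(k, []):
                other = mobile[j]
                if other.wntpcp_positive and other.oi_axis is not None:
                    if ref is None:
                        ref = other.oi_axis
                    sgn = 1.0 if np.dot(other.oi_axis, ref) >= 0 else -1.0
                    s += sgn * other.oi_axis
            nrm = np.linalg.norm(s)
            if nrm > 1e-12:
                c.oi_axis = s / nrm
            else:
                xy = np.asarray(c.xy, dtype=float)
                nrm = np.linalg.norm(xy)
                c.oi_axis = xy / nrm if nrm > 0 else np.array([0.0, 1.0])


def _vertical_phase(state: EmbryoState, log: SimulationLog | None) -> None:
    mobile_fields = getattr(state, "_fields_cache", None)
    levels: dict[int, float] = {}
    if mobile_fields is not None:
        mobile, fields = mobile_fields
        for k, c in enumerate(mobile):
            levels[c.id] = float(fields["nodal_level"][k])
    for c in sorted(
        (c for c in state.cells if c.kind == "emt"), key=lambda c: c.id
    ):
        emt_dynamics.vertical_step(c, state, log, level=levels.get(c.id))


def _cycle_phase(state: EmbryoState, log: SimulationLog | None) -> None:
    p = state.params
    dt = p.dt_hr
    new_cells = []
    divided = set()
    for c in state.cells:
        if c.kind != "epithelium":
            continue
        cell_cycle.regrow_radius(c, dt, p)
        if cell_cycle.advance_cycle(c, dt):
            ids = (state.allocate_id(), state.allocate_id())
            d1, d2 = cell_cycle.divide(c, state.rng, p, ids)
            new_cells.extend([d1, d2])
            divided.add(c.id)
            if log is not None:
                log.record_event(state.tick, c.id, "division")
    if divided:
        state.cells = [c for c in state.cells if c.id not in divided] + new_cells


def step(state: EmbryoState, log: SimulationLog | None = None) -> EmbryoState:
    """Advance the embryo by one tick (10 min), in place."""
    p = state.params
    tick = state.tick

    state.lower = advance_lower_layer(state.lower, tick, p)
    # the hypoblast is a circular domain of similar dimensions as the
    # epiblast: its footprint tracks the growing MZ ring
    ring_r = float(
        np.max(np.linalg.norm(state.mz_ring.points - state.mz_ring.centroid, axis=1))
    )
    if ring_r > state.lower.disc_radius:
        from dataclasses import replace

        state.lower = replace(state.lower, disc_radius=ring_r)

    in_plane = state.in_plane_cells()
    cells_area = float(sum(np.pi * c.radius**2 for c in in_plane))
    target = target_epiblast_area(state.mz_ring, cells_area, state.time_hr, p)
    apply_mz_displacement(state, target)
    resample_ring(state.mz_ring)
    state.invalidate_tessellation()

    _conversion_phase(state, log)
    _vertical_phase(state, log)
    _cycle_phase(state, log)
    planar_motion.run_equilibration(state)
    planar_motion.oi_consensus_update(state)

    state.tick = tick + 1
    state.time_hr = state.tick * p.dt_hr
    if log is not None:
        log.record_snapshot(state)
    return state


def run(scenario, seed: int) -> SimulationLog:
    """Run a scenario to completion and return its full log.

    Initializes the embryo from the scenario's parameters, applies any
    scheduled perturbations at their ticks, executes ``total_ticks`` steps
    and logs one snapshot per tick (plus the initial state).
    """
    from . import experiments

    params = scenario.params
    state = initialize_embryo(params, seed)
    log = SimulationLog()
    by_tick: dict[int, list] = {}
    for pert in scenario.perturbations:
        if not (0 <= pert.tick <= params.total_ticks):
            raise ValueError(f"perturbation tick {pert.tick} outside run")
        by_tick.setdefault(pert.tick, []).append(pert)

    for pert in by_tick.get(0, []):
        experiments.apply_perturbation(state, pert, log)
    log.record_snapshot(state)

    for _ in range(params.total_ticks):
        step(state, log)
        for pert in by_tick.get(state.tick, []):
            experiments.apply_perturbation(state, pert, log)

    log.final_state = state
    return log
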