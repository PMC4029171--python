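"""Scenario definitions for the simulated experiments and parameter sweeps.

Four in-silico experiments probe the model:

* **normal** — default parameters; produces the posterior midline streak
  and the bilateral "Polonaise" counter-rotation.
* **pcp_block** — oriented intercalation abolished in a fraction of the
  streak-forming cohort (mimicking PCP loss-of-function); with strong
  block, ingression concentrates near the posterior margin instead of the
  midline and lateral cells travel along straightened paths.
* **graft** — a clump of Nodal-positive ingressing cells placed under a
  lateral site before streak formation induces an ectopic ingression zone
  from host cells (no induction when Nodal conversion is disabled,
  mimicking Nodal-inhibitor beads).
* **extra_oi_domain** — a supplementary Wnt-PCP/OI domain (mimicking
  hypoblast rotation) bends the forming streak.

A sweep over the community-effect midpoint m_N and effector range sigma_d
(with d_max kept at 4 sigma_d) probes ingression kinetics.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from matplotlib.path import Path as MplPath

from .mathkit import KernelParams, LogisticParams
from .model_state import Cell, EmbryoState, Params

__all__ = [
    "Perturbation",
    "ScenarioConfig",
    "scenario_normal",
    "scenario_pcp_block",
    "scenario_graft",
    "scenario_extra_oi_domain",
    "sweep_community_effect",
    "disable_nodal_conversion",
    "scaled_params",
    "apply_perturbation",
]


@dataclass(frozen=True)
class Perturbation:
    tick: int
    kind: str  # one of {"pcp_block", "graft", "extra_oi_domain"}
    payload: dict = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    name: str
    params: Params
    perturbations: list[Perturbation] = field(default_factory=list)


def _base_params(params: Optional[Params]) -> Params:
    return copy.deepcopy(params) if params is not None else Params()


def scenario_normal(params: Optional[Params] = None) -> ScenarioConfig:
    """Unperturbed development from stage XI to stage 3+."""
    return ScenarioConfig(name="normal", params=_base_params(params))


def scenario_pcp_block(fraction: float, params: Optional[Params] = None) -> ScenarioConfig:
    """Abolish oriented intercalation in a random fraction of the SAE cohort.

    Blocked cells neither execute OI nor contribute to the consensus or to
    their neighbours' intercalation; their Nodal behaviour is untouched.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return ScenarioConfig(
        name=f"pcp_block_{fraction:g}",
        params=_base_params(params),
        perturbations=[Perturbation(tick=0, kind="pcp_block", payload={"fraction": fraction})],
    )


def scenario_graft(
    n_cells: int = 15,
    site: Optional[tuple[float, float]] = None,
    tick: int = 6,
    params: Optional[Params] = None,
) -> ScenarioConfig:
    """Graft Nodal-positive ingressing cells under a lateral epiblast site.

    ``site=None`` places the graft at 55% of the disc radius on the right
    lateral side.  Grafted cells are static tethered-EMT Nodal sources at
    -8 μm depth, exempt from reversion.
    """
    return ScenarioConfig(
        name="graft",
        params=_base_params(params),
        perturbations=[
            Perturbation(tick=tick, kind="graft", payload={"n_cells": n_cells, "site": site})
        ],
    )


def scenario_extra_oi_domain(
    polygon: Optional[np.ndarray] = None,
    tick: int = 12,
    params: Optional[Params] = None,
) -> ScenarioConfig:
    """Add a supplementary Wnt-PCP/OI domain (hypoblast-rotation mimic).

    Epithelial cells inside the polygon become Wnt-PCP-positive at ``tick``
    regardless of Nodal state.  ``polygon=None`` selects a default
    anterior-lateral crescent.
    """
    payload = {"polygon": None if polygon is None else np.asarray(polygon, dtype=float)}
    return ScenarioConfig(
        name="extra_oi_domain",
        params=_base_params(params),
        perturbations=[Perturbation(tick=tick, kind="extra_oi_domain", payload=payload)],
    )


def disable_nodal_conversion(params: Params) -> Params:
    """Return a copy of ``params`` with Nodal propagation switched off."""
    p = copy.deepcopy(params)
    lp = p.nodal_conv.logistic
    p.nodal_conv.logistic = LogisticParams(p_min=0.0, p_max=0.0, m=lp.m, s=lp.s)
    return p


def sweep_community_effect(
    m_n_values=(6.0, 7.0, 8.0, 9.0, 10.0),
    sigma_d_values=(5.0, 10.0, 15.0, 20.0),
    params: Optional[Params] = None,
) -> list[ScenarioConfig]:
    """Grid of scenarios varying the EMT community-effect parameters.

    ``m_N`` shifts the logistic midpoint of the ingression hazard;
    ``sigma_d`` sets the spatial range of effector cells, with the cutoff
    co-modified to remain d_max = 4 sigma_d.
    """
    if min(m_n_values) <= 0 or min(sigma_d_values) <= 0:
        raise ValueError("sweep values must be positive")
    out = []
    for m_n in m_n_values:
        for sig in sigma_d_values:
            p = _base_params(params)
            lp = p.emt.logistic
            p.emt.logistic = LogisticParams(p_min=lp.p_min, p_max=lp.p_max, m=float(m_n), s=lp.s)
            p.emt.kernel = KernelParams(sigma_d=float(sig), d_max=4.0 * float(sig))
            out.append(
                ScenarioConfig(name=f"sweep_mN{m_n:g}_sd{sig:g}", params=p)
            )
    return out


def scaled_params(
    n_cells: int = 300,
    equil_iters: int = 100,
    base: Optional[Params] = None,
) -> Params:
    """A reduced-size configuration for desk-scale runs.

    Keeps the model constants at their defaults but shrinks the tissue to
    ``n_cells`` (with the streak-forming cohort scaled proportionally) and
    reduces the tessellation-rebuild count per tick, compensating with OI
    micro-substeps so the intercalation rate per tick matches the default
    sub-iteration budget.  Lloyd relaxation is far past convergence at
    either setting, so the mechanics are unchanged.
    """
    p = copy.deepcopy(base) if base is not None else Params()
    frac = n_cells / p.n_initial_epiblast
    p.n_initial_sae = max(1, int(round(p.n_initial_sae * frac)))
    p.n_initial_epiblast = n_cells
    p.oi_substeps = max(1, round(p.equil_iters_per_tick / equil_iters))
    p.equil_iters_per_tick = equil_iters
    return p


# ---------------------------------------------------------------------------
# perturbation application (called by the engine at the scheduled tick)


def apply_perturbation(state: EmbryoState, pert: Perturbation, log=None) -> None:
    if pert.kind == "pcp_block":
        _apply_pcp_block(state, pert.payload["fraction"])
    elif pert.kind == "graft":
        _apply_graft(state, pert.payload.get("n_cells", 15), pert.payload.get("site"), log)
    elif pert.kind == "extra_oi_domain":
        _apply_extra_oi_domain(state, pert.payload.get("polygon"))
    else:
        raise ValueError(f"unknown perturbation kind {pert.kind!r}")


def _apply_pcp_block(state: EmbryoState, fraction: float) -> None:
    cohort = [c for c in state.cells if c.wntpcp_positive and not c.oi_blocked]
    n_block = int(round(fraction * len(cohort)))
    idx = state.rng.choice(len(cohort), size=n_block, replace=False) if n_block else []
    for k in idx:
        cohort[k].oi_blocked = True


def _default_graft_site(state: EmbryoState) -> np.ndarray:
    return np.array([0.55 * state.lower.disc_radius, 0.0])


def _apply_graft(state: EmbryoState, n_cells: int, site, log=None) -> None:
    xy0 = np.asarray(site, dtype=float) if site is not None else _default_graft_site(state)
    if float(np.hypot(*xy0)) >= state.lower.disc_radius:
        raise ValueError("graft site lies outside the embryonic disc")
    # compact hexagonal clump around the site
    r = state.params.cell_radius_um
    offsets = [np.zeros(2)]
    ring_n = 1
    while len(offsets) < n_cells:
        for k in range(6 * ring_n):
            a = 2.0 * np.pi * k / (6 * ring_n)
            offsets.append(ring_n * 2.0 * r * np.array([np.cos(a), np.sin(a)]))
        ring_n += 1
    for k in range(n_cells):
        cid = state.allocate_id()
        state.cells.append(
            Cell(
                id=cid,
                xy=xy0 + offsets[k],
                z=-8.0,
                radius=r,
                kind="emt",
                tethered=True,
                vertical_direction="descending",
                nodal_positive=True,
                graft=True,
            )
        )
        if log is not None:
            log.record_event(state.tick, cid, "graft")
    state.invalidate_tessellation()


def _default_extra_oi_polygon(state: EmbryoState) -> np.ndarray:
    """Anterior-lateral crescent: a wedge of the disc centred at +45 deg."""
    r_out = state.lower.disc_radius
    r_in = 0.55 * r_out
    ang = np.linspace(np.deg2rad(10.0), np.deg2rad(80.0), 24)
    outer = r_out * np.column_stack([np.cos(ang), np.sin(ang)])
    inner = r_in * np.column_stack([np.cos(ang[::-1]), np.sin(ang[::-1])])
    return np.vstack([outer, inner])


def _apply_extra_oi_domain(state: EmbryoState, polygon) -> None:
    poly = (
        np.asarray(polygon, dtype=float)
        if polygon is not None
        else _default_extra_oi_polygon(state)
    )
    if poly.shape[0] >= 3:
        path = MplPath(poly)
        targets = [
            c
            for c in state.cells
            if c.kind == "epithelium" and path.contains_point(np.asarray(c.xy, dtype=float))
        ]
    else:
        targets = []
    for c in targets:
        if not c.wntpcp_positive:
            c.wntpcp_positive = True
            xy = np.asarray(c.xy, dtype=float)
            nrm = np.linalg.norm(xy)
            c.oi_axis = xy / nrm if nrm > 0 else np.array([0.0, 1.0])
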