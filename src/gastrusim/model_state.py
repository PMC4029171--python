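"""Domain types for cells, parameters, embryo state and simulation logs.

This module is the single source of truth for every model constant.  The
defaults in :class:`Params` are the published values of the gastrulation
model: the logistic hazard tables for EMT tether dynamics and state
conversions, the effector coefficient sets with and without hypoblast
inhibition, the marginal-zone displacement constants, and the engine
settings (10-minute ticks, 1000 equilibration iterations per tick, 72
ticks ~ 12 h of development from stage XI to stage 3+).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lower_layer import LowerLayer, make_lower_layer
from .marginal_zone import MarginalZoneRing
from .mathkit import KernelParams, LogisticParams
from .signalling import EffectorCoefficients

__all__ = [
    "Cell",
    "Params",
    "MzParams",
    "ConversionParams",
    "EmbryoState",
    "SimulationLog",
    "initialize_embryo",
    "census",
    "params_from_dict",
    "params_to_dict",
]

HEX_PACKING_FRACTION = math.sqrt(3.0) * math.pi / 6.0  # ~0.9069


@dataclass(slots=True)
class Cell:
    """One model agent.

    Positions are in μm in the embryo plane (+y anterior, -y posterior);
    ``z`` is depth below the epithelial plane (0 = in plane, negative =
    below).  For a tethered EMT cell ``xy`` is the in-plane tether point.
    ``oi_axis`` is a nematic planar unit axis (no head/tail) used by
    oriented intercalation; it is meaningful only for Wnt-PCP-positive
    cells.
    """

    id: int
    xy: np.ndarray
    z: float = 0.0
    radius: float = 5.0
    kind: str = "epithelium"  # one of {"MZ", "epithelium", "emt", "meso"}
    tethered: bool = False
    vertical_direction: Optional[str] = None  # "ascending" | "descending"
    nodal_positive: bool = False
    wntpcp_positive: bool = False
    oi_axis: Optional[np.ndarray] = None
    oi_blocked: bool = False
    cycle_age: float = 0.0
    cycle_length: float = 6.0
    parent_id: Optional[int] = None
    graft: bool = False  # grafted Nodal source: static, reversion-exempt


# ---------------------------------------------------------------------------
# parameters


@dataclass
class MzParams:
    """Marginal-zone displacement constants (curvature / density / area)."""

    k_curv: float = 70.0
    k_dens: float = 0.10
    d_max: float = 55.0  # μm, density-kernel cutoff
    sigma_d: float = 15.0  # μm, density-kernel width
    k_area: float = 0.15  # density-rise amplitude of the area schedule
    k_t: float = 4.0  # hr, time scale of the area schedule
    area_gain: float = 1.0  # proportional gain of the area controller
    spacing_target_um: float = 10.0  # pseudo-cell spacing (one cell diameter)


@dataclass
class ConversionParams:
    """A logistic hazard plus its effector-coefficient tables."""

    logistic: LogisticParams
    kernel: KernelParams
    active: EffectorCoefficients  # receiver not inhibited by hypoblast
    inactive: EffectorCoefficients  # receiver under the hypoblast


def _default_emt() -> ConversionParams:
    return ConversionParams(
        logistic=LogisticParams(p_min=0.02, p_max=0.999, m=8.0, s=1.0),
        kernel=KernelParams(sigma_d=10.0, d_max=40.0),
        active=EffectorCoefficients(k_self=1.0, k_nn=1.0, k_n=1.0),
        inactive=EffectorCoefficients(k_self=0.6, k_nn=0.6, k_n=0.0),
    )


def _default_nodal_conv() -> ConversionParams:
    return ConversionParams(
        logistic=LogisticParams(p_min=0.0, p_max=0.999, m=2.0, s=0.25),
        kernel=KernelParams(sigma_d=10.0, d_max=40.0),
        active=EffectorCoefficients(k_self=0.0, k_nn=1.0, k_n=1.0),
        inactive=EffectorCoefficients(k_self=0.0, k_nn=0.6, k_n=0.0),
    )


def _default_wntpcp_conv() -> ConversionParams:
    return ConversionParams(
        logistic=LogisticParams(p_min=0.0, p_max=0.999, m=1.0, s=0.25),
        kernel=KernelParams(sigma_d=10.0, d_max=40.0),
        active=EffectorCoefficients(k_self=0.0, k_nn=1.0, k_n=1.0),
        inactive=EffectorCoefficients(k_self=0.0, k_nn=0.6, k_n=0.0),
    )


@dataclass
class Params:
    """Every model constant, defaulting to the published values."""

    # time / space
    tick_minutes: float = 10.0
    click_um: float = 1.0
    total_ticks: int = 72

    # initial conditions
    cell_radius_um: float = 5.0
    n_initial_epiblast: int = 1000
    n_initial_sae: int = 95
    sae_half_angle_deg: float = 85.0  # thin sickle: ~2 rows hugging the margin
    init_jitter_um: float = 0.3

    # cell cycle
    mean_cycle_hr: float = 6.0
    cycle_cv: float = 0.10
    regrowth_hr: float = 1.0

    # marginal zone
    mz: MzParams = field(default_factory=MzParams)

    # EMT tether dynamics (depth-dependent hazards, z in μm)
    dirchange_up: LogisticParams = field(
        default_factory=lambda: LogisticParams(p_min=0.8, p_max=0.0, m=-5.0, s=1.0)
    )
    dirchange_down: LogisticParams = field(
        default_factory=lambda: LogisticParams(p_min=0.0, p_max=0.4, m=-5.0, s=1.0)
    )
    reversion: LogisticParams = field(
        default_factory=lambda: LogisticParams(p_min=0.30, p_max=0.90, m=-5.0, s=1.5)
    )
    untether: LogisticParams = field(
        default_factory=lambda: LogisticParams(p_min=0.0, p_max=0.999, m=-12.5, s=1.0)
    )

    # state conversions
    emt: ConversionParams = field(default_factory=_default_emt)
    nodal_conv: ConversionParams = field(default_factory=_default_nodal_conv)
    wntpcp_conv: ConversionParams = field(default_factory=_default_wntpcp_conv)
    nodal_reversion_threshold: float = 1.0

    # planar motion
    equil_iters_per_tick: int = 1000
    oi_step_um: float = 1.0  # |sin theta| displacement scale, μm/sub-iteration
    oi_substeps: int = 1  # OI micro-updates per tessellation rebuild

    # vertical motion
    vertical_speed_um_per_tick: float = 2.5
    meso_depth_um: float = -25.0

    # lower-layer schedule
    endoblast_start_tick: int = 30
    endoblast_front_speed_frac: float = 0.06  # of disc diameter, per tick
    endoblast_stop_y_frac: float = -0.3  # of disc radius

    @property
    def dt_hr(self) -> float:
        return self.tick_minutes / 60.0

    @property
    def bm_depth_um(self) -> float:
        """Basement-membrane depth: a cell is fully below the BM at z < -2r."""
        return -2.0 * self.cell_radius_um

    def validate(self) -> None:
        if self.n_initial_sae > self.n_initial_epiblast:
            raise ValueError("n_initial_sae cannot exceed n_initial_epiblast")
        if self.total_ticks < 0 or self.equil_iters_per_tick < 0:
            raise ValueError("tick counts must be non-negative")


# ---------------------------------------------------------------------------
# config (de)serialization — JSON mirroring the field names, unknown keys
# rejected


def params_to_dict(p) -> dict:
    if dataclasses.is_dataclass(p):
        return {
            f.name: params_to_dict(getattr(p, f.name)) for f in dataclasses.fields(p)
        }
    return p


def _from_dict(cls, d: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        target = {
            "mz": MzParams,
            "emt": ConversionParams,
            "nodal_conv": ConversionParams,
            "wntpcp_conv": ConversionParams,
            "logistic": LogisticParams,
            "kernel": KernelParams,
            "active": EffectorCoefficients,
            "inactive": EffectorCoefficients,
            "dirchange_up": LogisticParams,
            "dirchange_down": LogisticParams,
            "reversion": LogisticParams,
            "untether": LogisticParams,
        }.get(name)
        if target is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(target, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def params_from_dict(d: dict) -> Params:
    """Build Params from a (possibly partial) nested dict; unknown keys error."""
    base = params_to_dict(Params())

    def merge(default: dict, override: dict, cls) -> dict:
        unknown = set(override) - set(default)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = dict(default)
        for k, v in override.items():
            if isinstance(v, dict) and isinstance(default[k], dict):
                out[k] = merge(default[k], v, None)
            else:
                out[k] = v
        return out

    return _from_dict(Params, merge(base, d, Params))


def load_params_json(path) -> Params:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# embryo state


@dataclass
class EmbryoState:
    tick: int
    time_hr: float
    cells: list[Cell]
    mz_ring: MarginalZoneRing
    lower: LowerLayer
    rng: np.random.Generator
    params: Params
    next_id: int = 0
    _tess: object = None

    def in_plane_cells(self) -> list[Cell]:
        return [
            c
            for c in self.cells
            if c.kind == "epithelium" or (c.kind == "emt" and c.tethered)
        ]

    def allocate_id(self) -> int:
        out = self.next_id
        self.next_id += 1
        return out

    def tessellation(self, rebuild: bool = False):
        """Current pseudo-Voronoi tessellation (cached per tick)."""
        from .geometry import build_tessellation

        if self._tess is None or rebuild:
            self._tess = build_tessellation(self)
        return self._tess

    def invalidate_tessellation(self) -> None:
        self._tess = None


def census(state: EmbryoState) -> dict[str, int]:
    """Counts by kind and signalling state."""
    out = {
        "epithelium": 0,
        "t_emt": 0,
        "u_emt": 0,
        "meso": 0,
        "MZ": state.mz_ring.points.shape[0],
        "nodal_pos": 0,
        "wntpcp_pos": 0,
    }
    for c in state.cells:
        if c.kind == "epithelium":
            out["epithelium"] += 1
        elif c.kind == "emt":
            out["t_emt" if c.tethered else "u_emt"] += 1
        elif c.kind == "meso":
            out["meso"] += 1
        if c.nodal_positive:
            out["nodal_pos"] += 1
        if c.wntpcp_positive:
            out["wntpcp_pos"] += 1
    return out


# ---------------------------------------------------------------------------
# initialization


def draw_cycle_lengths(p: Params, rng: np.random.Generator, n: int) -> np.ndarray:
    """Cycle lengths from a normal truncated at +-3 SD (mean 6 hr, CV 10%)."""
    sd = p.cycle_cv * p.mean_cycle_hr
    out = rng.normal(p.mean_cycle_hr, sd, size=n)
    bad = np.abs(out - p.mean_cycle_hr) > 3.0 * sd
    while bad.any():
        out[bad] = rng.normal(p.mean_cycle_hr, sd, size=int(bad.sum()))
        bad = np.abs(out - p.mean_cycle_hr) > 3.0 * sd
    return out


def _hex_disc(n: int, spacing: float) -> np.ndarray:
    """The n hexagonal-lattice points closest to the origin."""
    m = int(math.ceil(math.sqrt(n / HEX_PACKING_FRACTION))) + 3
    cols = np.arange(-m, m + 1)
    rows = np.arange(-m, m + 1)
    xx = []
    for r in rows:
        x = (cols + 0.5 * (r % 2)) * spacing
        y = np.full_like(x, r * spacing * math.sqrt(3.0) / 2.0)
        xx.append(np.column_stack([x, y]))
    pts = np.vstack(xx)
    d2 = np.einsum("ij,ij->i", pts, pts)
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(d2, 9)))
    return pts[order[:n]]


def initialize_embryo(params: Params, seed: int) -> EmbryoState:
    """Build the stage-XI embryo: an epiblast disc, MZ ring, SAE cohort.

    The epiblast is a hexagonally packed disc of ``n_initial_epiblast``
    epithelial cells with a small positional jitter; its radius follows
    from the cell count and the hexagonal packing fraction.  A ring of MZ
    pseudo-cells encircles it.  The ``n_initial_sae`` cells nearest the
    posterior margin within a +-60 deg wedge about the posterior pole form
    the streak-forming (SAE) cohort: Nodal- and Wnt-PCP-positive with
    intercalation axes perpendicular to the local marginal zone.  The
    hypoblast covers the whole disc; there are no EMT or meso cells.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(seed)
    n = p.n_initial_epiblast
    r = p.cell_radius_um

    spacing = 2.0 * r
    pts = _hex_disc(n, spacing)
    jit_r = p.init_jitter_um * np.sqrt(rng.random(n))
    jit_a = rng.random(n) * 2.0 * np.pi
    pts = pts + np.column_stack([jit_r * np.cos(jit_a), jit_r * np.sin(jit_a)])

    disc_radius = r * math.sqrt(n / HEX_PACKING_FRACTION)
    ring_radius = disc_radius + 2.0 * r
    n_ring = max(8, int(round(2.0 * np.pi * ring_radius / p.mz.spacing_target_um)))
    ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring_pts = ring_radius * np.column_stack([np.cos(ang), np.sin(ang)])

    cells_area = n * np.pi * r * r
    ring = MarginalZoneRing(
        points=ring_pts,
        spacing_target=p.mz.spacing_target_um,
        initial_cells_area=cells_area,
    )

    cycle_lengths = draw_cycle_lengths(p, rng, n)
    ages = rng.random(n) * cycle_lengths

    cells = [
        Cell(
            id=i,
            xy=pts[i].copy(),
            radius=r,
            kind="epithelium",
            cycle_age=float(ages[i]),
            cycle_length=float(cycle_lengths[i]),
        )
        for i in range(n)
    ]

    # SAE cohort: wedge about the posterior pole, margin-nearest cells first
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    dphi = np.abs(np.angle(np.exp(1j * (phi + np.pi / 2.0))))
    in_wedge = dphi <= np.deg2rad(p.sae_half_angle_deg)
    margin_dist = ring_radius - np.hypot(pts[:, 0], pts[:, 1])
    order = np.lexsort((dphi, np.round(margin_dist, 6)))
    chosen = [i for i in order if in_wedge[i]][: p.n_initial_sae]
    for i in chosen:
        c = cells[i]
        c.nodal_positive = True
        c.wntpcp_positive = True
        rad = np.asarray(c.xy, dtype=float)
        nrm = np.linalg.norm(rad)
        c.oi_axis = rad / nrm if nrm > 0 else np.array([0.0, 1.0])

    lower = make_lower_layer(ring_radius)
    return EmbryoState(
        tick=0,
        time_hr=0.0,
        cells=cells,
        mz_ring=ring,
        lower=lower,
        rng=rng,
        params=p,
        next_id=n,
    )


# ---------------------------------------------------------------------------
# simulation log


@dataclass
class SimulationLog:
    """Per-tick snapshots, discrete events, and derived trails."""

    snapshots: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    final_state: Optional[EmbryoState] = None

    def record_snapshot(self, state: EmbryoState) -> None:
        cells = state.cells
        n = len(cells)
        snap = {
            "tick": state.tick,
            "cell_id": np.fromiter((c.id for c in cells), dtype=np.int64, count=n),
            "x": np.fromiter((c.xy[0] for c in cells), dtype=float, count=n),
            "y": np.fromiter((c.xy[1] for c in cells), dtype=float, count=n),
            "z": np.fromiter((c.z for c in cells), dtype=float, count=n),
            "radius": np.fromiter((c.radius for c in cells), dtype=float, count=n),
            "kind": np.array([c.kind for c in cells]),
            "tethered": np.fromiter((c.tethered for c in cells), dtype=bool, count=n),
            "direction": np.array([c.vertical_direction or "" for c in cells]),
            "nodal": np.fromiter((c.nodal_positive for c in cells), dtype=bool, count=n),
            "wntpcp": np.fromiter((c.wntpcp_positive for c in cells), dtype=bool, count=n),
            "oi_angle": np.fromiter(
                (
                    float(np.arctan2(c.oi_axis[1], c.oi_axis[0]) % np.pi)
                    if c.oi_axis is not None
                    else np.nan
                    for c in cells
                ),
                dtype=float,
                count=n,
            ),
            "oi_blocked": np.fromiter((c.oi_blocked for c in cells), dtype=bool, count=n),
            "parent_id": np.fromiter(
                (-1 if c.parent_id is None else c.parent_id for c in cells),
                dtype=np.int64,
                count=n,
            ),
        }
        self.snapshots.append(snap)

    def record_event(self, tick: int, cell_id: int, event: str) -> None:
        self.events.append({"tick": tick, "cell_id": cell_id, "event": event})

    def snapshot_frame(self):
        import pandas as pd

        frames = []
        for snap in self.snapshots:
            df = pd.DataFrame({k: v for k, v in snap.items() if k != "tick"})
            df.insert(0, "tick", snap["tick"])
            frames.append(df)
        if not frames:
            import pandas as pd

            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=["tick", "cell_id", "event"])

    def trails(self, window: Optional[tuple[int, int]] = None) -> dict[int, np.ndarray]:
        """Per-cell position history: cell_id -> (n_ticks, 3) [tick, x, y]."""
        out: dict[int, list] = {}
        for snap in self.snapshots:
            t = snap["tick"]
            if window is not None and not (window[0] <= t <= window[1]):
                continue
            for cid, x, y in zip(snap["cell_id"], snap["x"], snap["y"]):
                out.setdefault(int(cid), []).append((t, x, y))
        return {cid: np.asarray(v, dtype=float) for cid, v in out.items()}
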