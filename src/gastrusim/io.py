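"""Snapshot/event/trail serialization and simple frame rendering.

All outputs are plain CSV so that downstream analysis (the metrics module
or external tools) never needs live simulation state.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

SNAPSHOT_COLUMNS = [
    "tick",
    "cell_id",
    "x",
    "y",
    "z",
    "radius",
    "kind",
    "tethered",
    "direction",
    "nodal",
    "wntpcp",
    "oi_angle",
    "oi_blocked",
    "parent_id",
]

__all__ = [
    "SNAPSHOT_COLUMNS",
    "write_snapshot",
    "read_snapshot",
    "write_events",
    "export_trails",
    "render_frame",
]


def snapshot_frame_from_state(state) -> pd.DataFrame:
    from .model_state import SimulationLog

    log = SimulationLog()
    log.record_snapshot(state)
    return log.snapshot_frame()[SNAPSHOT_COLUMNS]


def write_snapshot(path, state_or_log) -> None:
    """Write per-cell snapshot rows (one row per cell per logged tick)."""
    if hasattr(state_or_log, "snapshot_frame"):
        df = state_or_log.snapshot_frame()
        if not df.empty:
            df = df[SNAPSHOT_COLUMNS]
    else:
        df = snapshot_frame_from_state(state_or_log)
    df.to_csv(path, index=False)


def read_snapshot(path) -> pd.DataFrame:
    """Read a snapshot CSV, validating the exact column set.

    ``oi_angle`` is the nematic axis angle in [0, pi) (NaN when the cell
    carries no axis).
    """
    df = pd.read_csv(path)
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SNAPSHOT_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"snapshot schema mismatch: missing columns {missing}, unexpected {extra}"
        )
    return df[SNAPSHOT_COLUMNS]


def write_events(path, log) -> None:
    log.events_frame().to_csv(path, index=False)


def export_trails(log, path, sample_fraction: float = 0.15, seed: int = 0) -> pd.DataFrame:
    """Write long-format trails (cell_id, tick, x, y) for a cell sample.

    A deterministic ``sample_fraction`` of cell ids (default 15%) is kept;
    fraction 1.0 exports every cell.
    """
    if not log.snapshots:
        raise ValueError("log has no snapshots")
    trails = log.trails()
    ids = sorted(trails)
    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n_keep = int(round(sample_fraction * len(ids)))
        keep = set(rng.choice(ids, size=n_keep, replace=False).tolist())
    else:
        keep = set(ids)
    rows = []
    for cid in ids:
        if cid not in keep:
            continue
        for t, x, y in trails[cid]:
            rows.append({"cell_id": cid, "tick": int(t), "x": x, "y": y})
    df = pd.DataFrame(rows, columns=["cell_id", "tick", "x", "y"])
    df.to_csv(path, index=False)
    return df


# colour code: Nodal red, Wnt-PCP yellow, both orange, EMT blue,
# Nodal+EMT purple, meso aquamarine, MZ green
def _cell_colour(kind: str, nodal: bool, wntpcp: bool) -> str:
    if kind == "meso":
        return "aquamarine"
    if kind == "emt":
        return "purple" if nodal else "blue"
    if nodal and wntpcp:
        return "orange"
    if nodal:
        return "red"
    if wntpcp:
        return "yellow"
    return "0.85"


def render_frame(state, view: str = "dorsal", path: Optional[str] = None):
    """Scatter view of the embryo with the standard colour code.

    ``view="dorsal"`` shows in-plane cells; ``view="ventral"`` additionally
    scales marker size by depth to visualise ingressing cells.  Returns the
    matplotlib figure (saved to ``path`` if given).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ring = state.mz_ring.points
    ax.plot(
        np.append(ring[:, 0], ring[0, 0]),
        np.append(ring[:, 1], ring[0, 1]),
        color="green",
        lw=2,
    )
    for c in state.cells:
        if view == "dorsal" and c.kind == "meso":
            continue
        colour = _cell_colour(c.kind, c.nodal_positive, c.wntpcp_positive)
        size = 12.0
        if view == "ventral" and c.z < 0:
            size = 12.0 + min(-c.z, 25.0)
        ax.scatter(c.xy[0], c.xy[1], s=size, c=colour, edgecolors="none")
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(f"tick {state.tick} ({state.time_hr:.1f} h), {view} view")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
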