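"""Neighbour-effect computation and Nodal / Wnt-PCP state conversion.

Every juxtacrine/paracrine interaction in the model funnels through a
single quantity, the "effective neighbour equivalents" N_eff of a
receiving cell: a weighted sum over (i) the cell itself, (ii) its
near-neighbours (cells sharing a tessellation edge) and (iii) more distant
local neighbours whose contribution decays with a Gaussian of distance.
Hypoblast-derived Cerberus inhibits Nodal signalling; this is modelled by
swapping in a weaker coefficient set for receivers that lie under the
hypoblast (near-neighbour weight 1.0 -> 0.6, local weight 1.0 -> 0.0).

Two code paths compute N_eff: a per-cell API (:func:`neighbour_effect` and
friends) and a vectorized whole-field version (:func:`compute_fields`)
used by the engine; the test suite checks them against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .lower_layer import hypoblast_covers, hypoblast_covers_many
from .mathkit import KernelParams, distance_weight, logistic_probability

__all__ = [
    "EffectorCoefficients",
    "neighbour_effect",
    "nodal_activity",
    "NodalActivity",
    "nodal_conversion_probability",
    "wntpcp_conversion_probability",
]


@dataclass(frozen=True)
class EffectorCoefficients:
    """Weights for the three effector classes of N_eff."""

    k_self: float
    k_nn: float
    k_n: float

    def __post_init__(self) -> None:
        if min(self.k_self, self.k_nn, self.k_n) < 0:
            raise ValueError("effector coefficients must be non-negative")


def neighbour_effect(
    cell,
    tess,
    effector_test: Callable,
    coeff: EffectorCoefficients,
    kp: KernelParams,
) -> float:
    """N_eff = k_self [self] + k_nn (#effector near-neighbours) + k_n sum w(d).

    Near-neighbours are the cells sharing a tessellation edge with ``cell``;
    local neighbours are every other (in-plane or untethered-EMT) cell at
    distance d < d_max, weighted by exp(-d^2 / (2 sigma_d^2)).
    """
    n_eff = coeff.k_self * (1.0 if effector_test(cell) else 0.0)
    nn = tess.near_neighbours(cell.id)
    n_nn = sum(
        1 for j in nn if j >= 0 and j in tess.cells and effector_test(tess.cells[j])
    )
    n_eff += coeff.k_nn * n_nn
    if coeff.k_n > 0.0:
        xy = np.asarray(cell.xy, dtype=float)
        local = 0.0
        for j, other in list(tess.cells.items()) + list(tess.offplane.items()):
            if j == cell.id or j in nn:
                continue
            if not effector_test(other):
                continue
            d = float(np.linalg.norm(np.asarray(other.xy) - xy))
            local += distance_weight(d, kp)
        n_eff += coeff.k_n * local
    return n_eff


def _is_nodal(c) -> bool:
    return bool(c.nodal_positive)


def _is_wntpcp(c) -> bool:
    return bool(c.wntpcp_positive)


@dataclass(frozen=True)
class NodalActivity:
    level: float
    receptive: bool
    active: bool


def nodal_activity(cell, state, tess=None) -> NodalActivity:
    """Integrated Nodal effect at a cell.

    ``receptive`` is False under the hypoblast (Cerberus inhibition);
    ``level`` is N_eff over Nodal-positive effectors with the coefficient
    set selected by receptivity; ``active`` requires receptivity and a
    positive level.
    """
    if tess is None:
        tess = state.tessellation()
    p = state.params
    receptive = not hypoblast_covers(state.lower, cell.xy)
    coeff = p.emt.active if receptive else p.emt.inactive
    level = neighbour_effect(cell, tess, _is_nodal, coeff, p.emt.kernel)
    return NodalActivity(level=level, receptive=receptive, active=receptive and level > 0.0)


def nodal_conversion_probability(cell, state, tess=None) -> float:
    """Per-hour probability that a Nodal-negative epithelial cell turns on Nodal."""
    if cell.nodal_positive:
        raise ValueError("cell is already Nodal-positive")
    if tess is None:
        tess = state.tessellation()
    p = state.params
    receptive = not hypoblast_covers(state.lower, cell.xy)
    coeff = p.nodal_conv.active if receptive else p.nodal_conv.inactive
    n_eff = neighbour_effect(cell, tess, _is_nodal, coeff, p.nodal_conv.kernel)
    return logistic_probability(n_eff, p.nodal_conv.logistic)


def wntpcp_conversion_probability(cell, state, tess=None) -> float:
    """Per-hour probability of Wnt-PCP activation; zero without prior Nodal."""
    if not cell.nodal_positive:
        return 0.0
    if tess is None:
        tess = state.tessellation()
    p = state.params
    receptive = not hypoblast_covers(state.lower, cell.xy)
    coeff = p.wntpcp_conv.active if receptive else p.wntpcp_conv.inactive
    n_eff = neighbour_effect(cell, tess, _is_wntpcp, coeff, p.wntpcp_conv.kernel)
    return logistic_probability(n_eff, p.wntpcp_conv.logistic)


# ---------------------------------------------------------------------------
# vectorized whole-field computation (engine hot path)


def compute_fields(
    pts_inplane: np.ndarray,
    pts_offplane: np.ndarray,
    nodal: np.ndarray,
    wntpcp: np.ndarray,
    edges: np.ndarray,
    lower,
    params,
) -> dict[str, np.ndarray]:
    """N_eff fields for every in-plane receiver, in one pass.

    ``nodal``/``wntpcp`` are effector indicators over the concatenation of
    in-plane and off-plane (untethered EMT) cells; ``edges`` are index pairs
    of in-plane near-neighbours.  Returns for each in-plane cell:

    - ``nodal_level``: N_eff with the self term (EMT conversion argument and
      the reversion-threshold quantity),
    - ``nodal_conv``: N_eff without the self term (Nodal conversion),
    - ``wnt_conv``: the same for Wnt-PCP effectors,
    - ``receptive``: hypoblast gating of each receiver.
    """
    n_in = pts_inplane.shape[0]
    all_pts = (
        np.vstack([pts_inplane, pts_offplane]) if pts_offplane.size else pts_inplane
    )
    nodal = np.asarray(nodal, dtype=float)
    wntpcp = np.asarray(wntpcp, dtype=float)
    receptive = ~hypoblast_covers_many(lower, pts_inplane)

    # near-neighbour effector counts (in-plane only)
    nn_nodal = np.zeros(n_in)
    nn_wnt = np.zeros(n_in)
    if edges.size:
        e = edges[(edges[:, 0] < n_in) & (edges[:, 1] < n_in)]
        np.add.at(nn_nodal, e[:, 0], nodal[e[:, 1]])
        np.add.at(nn_nodal, e[:, 1], nodal[e[:, 0]])
        np.add.at(nn_wnt, e[:, 0], wntpcp[e[:, 1]])
        np.add.at(nn_wnt, e[:, 1], wntpcp[e[:, 0]])

    # local (distance-weighted) sums, excluding self and near-neighbours
    kernels = {
        "emt": params.emt.kernel,
        "nodal": params.nodal_conv.kernel,
        "wnt": params.wntpcp_conv.kernel,
    }
    d_top = max(k.d_max for k in kernels.values())
    tree = cKDTree(all_pts)
    pairs = tree.query_pairs(d_top, output_type="ndarray")
    if pairs.size:
        dvec = all_pts[pairs[:, 0]] - all_pts[pairs[:, 1]]
        dist = np.hypot(dvec[:, 0], dvec[:, 1])
    else:
        dist = np.zeros(0)

    nn_set = set()
    if edges.size:
        for a, b in edges:
            if a < n_in and b < n_in:
                nn_set.add((min(a, b), max(a, b)))
    if pairs.size:
        is_nn = np.fromiter(
            ((min(a, b), max(a, b)) in nn_set for a, b in pairs),
            dtype=bool,
            count=pairs.shape[0],
        )
    else:
        is_nn = np.zeros(0, dtype=bool)

    def local_sum(kp: KernelParams, eff: np.ndarray) -> np.ndarray:
        out = np.zeros(n_in)
        if not pairs.size:
            return out
        w = np.exp(-(dist * dist) / (2.0 * kp.sigma_d**2))
        w[(dist >= kp.d_max) | is_nn] = 0.0
        a, b = pairs[:, 0], pairs[:, 1]
        mask_a = a < n_in
        np.add.at(out, a[mask_a], (w * eff[b])[mask_a])
        mask_b = b < n_in
        np.add.at(out, b[mask_b], (w * eff[a])[mask_b])
        return out

    def assemble(conv, nn_counts, local, self_ind=None):
        k_self = np.where(receptive, conv.active.k_self, conv.inactive.k_self)
        k_nn = np.where(receptive, conv.active.k_nn, conv.inactive.k_nn)
        k_n = np.where(receptive, conv.active.k_n, conv.inactive.k_n)
        out = k_nn * nn_counts + k_n * local
        if self_ind is not None:
            out = out + k_self * self_ind
        return out

    local_nodal_emt = local_sum(kernels["emt"], nodal)
    nodal_level = assemble(params.emt, nn_nodal, local_nodal_emt, nodal[:n_in])
    if kernels["nodal"] == kernels["emt"]:
        local_nodal_conv = local_nodal_emt
    else:
        local_nodal_conv = local_sum(kernels["nodal"], nodal)
    nodal_conv = assemble(params.nodal_conv, nn_nodal, local_nodal_conv)
    wnt_conv = assemble(params.wntpcp_conv, nn_wnt, local_sum(kernels["wnt"], wntpcp))

    return {
        "nodal_level": nodal_level,
        "nodal_conv": nodal_conv,
        "wnt_conv": wnt_conv,
        "receptive": receptive,
    }
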