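"""Shared numeric primitives for the stochastic cell-state machinery.

Every state conversion in the model (EMT initiation, tether reversion,
untethering, direction changes, Nodal and Wnt-PCP propagation) is a
per-hour hazard shaped by the same generalized logistic curve, and every
"local neighbour" influence is attenuated by the same truncated Gaussian
distance kernel.  Both primitives live here so that the printed model
constants are interpreted in exactly one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogisticParams",
    "KernelParams",
    "logistic_probability",
    "distance_weight",
    "per_tick_probability",
]


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of a bounded logistic hazard p(x).

    ``p_min`` is the asymptote as x -> -inf and ``p_max`` the asymptote as
    x -> +inf, both in probability per hour.  ``p_min > p_max`` is legal and
    used for hazards that *decrease* with their argument (e.g. the
    direction-change probability of ascending EMT cells).  ``m`` is the
    midpoint and ``s`` the slope scale, in units of the argument.
    """

    p_min: float
    p_max: float
    m: float
    s: float

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise ValueError(f"slope scale s must be > 0, got {self.s}")
        for name in ("p_min", "p_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class KernelParams:
    """Gaussian distance kernel with a hard cutoff.

    ``sigma_d`` is the Gaussian width and ``d_max`` the strict cutoff beyond
    which a neighbour contributes nothing, both in micrometres.
    """

    sigma_d: float
    d_max: float

    def __post_init__(self) -> None:
        if not (self.sigma_d > 0):
            raise ValueError(f"sigma_d must be > 0, got {self.sigma_d}")
        if not (self.d_max > 0):
            raise ValueError(f"d_max must be > 0, got {self.d_max}")


def logistic_probability(x: float, lp: LogisticParams) -> float:
    """Evaluate p_min + (p_max - p_min) / (1 + exp(-(x - m)/s)).

    Bounded between min(p_min, p_max) and max(p_min, p_max); monotone in x
    with direction set by the sign of (p_max - p_min).
    """
    if not np.isfinite(x):
        raise ValueError(f"logistic argument must be finite, got {x}")
    t = (x - lp.m) / lp.s
    # exp overflow guard: the curve saturates to its asymptote anyway.
    if t < -700.0:
        return lp.p_min
    if t > 700.0:
        return lp.p_max
    return lp.p_min + (lp.p_max - lp.p_min) / (1.0 + math.exp(-t))


def distance_weight(d: float, kp: KernelParams) -> float:
    """Gaussian weight exp(-d^2 / (2 sigma_d^2)) for d < d_max, else 0.

    The cutoff is strict: a neighbour at exactly d_max contributes nothing.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d >= kp.d_max:
        return 0.0
    return math.exp(-(d * d) / (2.0 * kp.sigma_d * kp.sigma_d))


def distance_weights(d: np.ndarray, kp: KernelParams) -> np.ndarray:
    """Vectorized :func:`distance_weight` for an array of distances."""
    d = np.asarray(d, dtype=float)
    w = np.exp(-(d * d) / (2.0 * kp.sigma_d * kp.sigma_d))
    w[d >= kp.d_max] = 0.0
    return w


def per_tick_probability(p_hr: float, dt: float) -> float:
    """Convert a per-hour probability into a per-tick probability.

    Uses survival-consistent geometric compounding,
    ``1 - (1 - p_hr)**dt``, so that compounding ``1/dt`` successive ticks
    reproduces the per-hour value exactly.  Linear scaling ``p_hr * dt``
    would be biased for the large hazards (0.999/hr) this model uses.
    """
    if not (0.0 <= p_hr <= 1.0):
        raise ValueError(f"p_hr must lie in [0, 1], got {p_hr}")
    if not (dt > 0):
        raise ValueError(f"dt must be > 0, got {dt}")
    if p_hr == 1.0:
        return 1.0
    return -math.expm1(dt * math.log1p(-p_hr))


def per_tick_probabilities(p_hr: np.ndarray, dt: float) -> np.ndarray:
    """Vectorized :func:`per_tick_probability` (assumes valid inputs)."""
    p = np.asarray(p_hr, dtype=float)
    out = -np.expm1(dt * np.log1p(-np.minimum(p, 1.0 - 1e-300)))
    out[p >= 1.0] = 1.0
    return out
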