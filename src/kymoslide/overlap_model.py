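"""Velocity-overlap relation and sliding-efficiency model.

The sliding velocity of a crosslinked microtubule pair saturates with the
overlap length L following a Michaelis-Menten-like law

    v = v0 * L / (L + K_L),                                             (1)

where K_L is the overlap length at half-maximal velocity. Mechanistically the
filament moves whenever at least one of the N sliding-competent crosslinking
complexes in the overlap is in its dual-bound configuration (probability S,
the *sliding efficiency*, the complex-level analog of a motor duty ratio):

    v = v0 * (1 - (1 - S)**N),                                          (2)

with N estimated from the fractional occupancy a of sliding-competent
complexes and the 8 nm binding-site length delta:

    N = a * L / delta.                                                  (4)

Evaluating (2) at L = K_L, where v = v0/2, gives the closed form

    S = 1 - 0.5**(1 / N(K_L)).                                          (3)

N is treated as a continuous quantity throughout (it is estimated from
lengths and intensities, not counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

DELTA_NM = 8.0  # length of a single binding site on the microtubule lattice


@dataclass(frozen=True)
class MMFit:
    """Result of fitting the saturating velocity-overlap relation."""

    v0: float
    kl: float
    cov: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if not (self.v0 > 0 and self.kl > 0):
            raise ValueError("v0 and KL must be positive")


@dataclass(frozen=True)
class EfficiencyParams:
    """(a, delta, N, S) tuple of the sliding-efficiency calculation."""

    occupancy: float
    delta: float
    n_complexes: float
    efficiency: float

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy a must lie in (0, 1]")
        if self.delta <= 0 or self.n_complexes <= 0:
            raise ValueError("delta and N must be positive")
        if not (0.0 < self.efficiency < 1.0):
            raise ValueError("efficiency S must lie in (0, 1)")


def mm_velocity(length, fit: MMFit):
    """Velocity (nm/s) at overlap length ``length`` (nm) under Eq. (1)."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("overlap length must be non-negative")
    out = fit.v0 * length / (length + fit.kl)
    return float(out) if out.ndim == 0 else out


def fit_mm(lengths, velocities) -> MMFit:
    """Unweighted nonlinear least squares of Eq. (1) on per-event points.

    Requires at least 4 points spanning a >= 2-fold range in overlap length.
    Initialization: v0 = max(v), KL = median(L); bounds keep both parameters
    positive and below 10x the data scale for stability on sparse data.
    """
    length = np.asarray(lengths, dtype=float)
    v = np.asarray(velocities, dtype=float)
    ok = np.isfinite(length) & np.isfinite(v)
    length, v = length[ok], v[ok]
    if length.size < 4:
        raise ValueError("need at least 4 finite (L, v) points")
    if length.min() <= 0 or length.max() / length.min() < 2.0:
        raise ValueError("overlap lengths must span at least a 2-fold range")

    def model(x, v0, kl):
        return v0 * x / (x + kl)

    p0 = (max(v.max(), 1e-6), float(np.median(length)))
    bounds = ([1e-9, 1e-9], [10.0 * v.max(), 10.0 * length.max()])
    popt, pcov = curve_fit(model, length, v, p0=p0, bounds=bounds, maxfev=10000)
    v0, kl = popt
    rel = 1e-6
    if kl >= bounds[1][1] * (1 - rel) or v0 >= bounds[1][0] * (1 - rel):
        raise RuntimeError(
            f"velocity-overlap fit hit its bounds (v0={v0:.3g}, KL={kl:.3g}); "
            "the data may not constrain the saturation"
        )
    return MMFit(v0=float(v0), kl=float(kl), cov=pcov, n_points=int(length.size))


def ensemble_velocity(v0: float, efficiency: float, n: float) -> float:
    """Eq. (2): v = v0 * (1 - (1 - S)**N); N may be non-integer."""
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency S must lie in [0, 1]")
    if n < 0:
        raise ValueError("N must be non-negative")
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    return v0 * (1.0 - (1.0 - efficiency) ** n)


def n_from_overlap(occupancy: float, length: float, delta: float = DELTA_NM) -> float:
    """Eq. (4): N = a * L / delta."""
    if not (occupancy > 0 and length > 0 and delta > 0):
        raise ValueError("a, L and delta must be positive")
    return occupancy * length / delta


def efficiency(kl: float, occupancy: float, delta: float = DELTA_NM) -> EfficiencyParams:
    """Eq. (3): solve (1 - S)**N = 1/2 with N = a * KL / delta."""
    n = n_from_overlap(occupancy, kl, delta)
    s = 1.0 - 0.5 ** (1.0 / n)
    return EfficiencyParams(occupancy=occupancy, delta=delta, n_complexes=n, efficiency=s)


def efficiency_table(kl: float, occupancies, delta: float = DELTA_NM):
    """Sliding efficiency S over a grid of occupancies a (returns DataFrame)."""
    import pandas as pd

    rows = [
        {
            "a": a,
            "N": (e := efficiency(kl, a, delta)).n_complexes,
            "S": e.efficiency,
        }
        for a in occupancies
    ]
    return pd.DataFrame(rows)


def predict_final_overlap(let1: float, let2: float, occupancy_factor: float = 1.0) -> float:
    """Roadblock prediction: L_FO = occupancy_factor * (LET1 + LET2).

    With saturated end-tags the stall leaves the full summed end-tag length as
    the final overlap (factor 1); sub-saturated end-tags permit further
    sliding after collision (factor < 1).
    """
    if let1 < 0 or let2 < 0:
        raise ValueError("end-tag lengths must be non-negative")
    if not (0.0 < occupancy_factor <= 1.0):
        raise ValueError("occupancy_factor must lie in (0, 1]")
    return occupancy_factor * (let1 + let2)
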