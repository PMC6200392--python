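"""Sliding velocity and three-phase segmentation.

The instantaneous sliding velocity is the time derivative of the moving
end-tag's outer edge position. Sliding events show three kinetic phases:
(1) constant velocity, (2) slowdown as the end-tags approach, (3) stall.
`segment_phases` fits a continuous piecewise model

    v(t) = v1                     for t <= t12
    v(t) = v1 * (t23-t)/(t23-t12) for t12 < t < t23
    v(t) = 0                      for t >= t23

to the velocity trace by least squares over an exhaustive changepoint grid,
with BIC comparison against the nested zero- and one-changepoint models so
degenerate records (no slowdown within the record, or stalled throughout) are
reported as such rather than forced into three phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .kymoquant import EdgeTrace, EventTrace


@dataclass
class VelocityTrace:
    """Instantaneous velocity (nm/s) on the frames of an edge trace."""

    t: np.ndarray
    v: np.ndarray
    window: int
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")


@dataclass
class PhaseSegmentation:
    """Changepoints (s) and phase-1 velocity of one event.

    ``t12 == t23 == t[-1]`` encodes a pure phase-1 record and
    ``t12 == t23 == t[0]`` a record stalled throughout; ``model`` names the
    BIC-selected variant and ``score`` is the residual sum of squares.
    """

    t12: float
    t23: float
    v_phase1: float
    score: float
    model: str
    n: int

    def __post_init__(self) -> None:
        if not (self.t12 <= self.t23 + 1e-12):
            raise ValueError("changepoints must satisfy t12 <= t23")


def instantaneous_velocity(edge: EdgeTrace, frame_interval: float,
                           window: int = 5) -> VelocityTrace:
    """Central-difference derivative of the moving-average-smoothed position.

    ``window`` must be odd and >= 3 and smaller than the trace; endpoints use
    one-sided differences (`numpy.gradient`). Velocities are defined on the
    same frame grid as the edge trace.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(edge.x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 tracked frames")
    if window >= x.size:
        raise ValueError("window must be smaller than the trace length")
    t = edge.frames * frame_interval
    # order-1 Savitzky-Golay == moving average in the interior, but preserves
    # a linear trend at the trace boundaries (a plain windowed mean biases the
    # first/last half-window of a moving edge)
    xs = savgol_filter(x, window_length=window, polyorder=1, mode="interp")
    v = np.gradient(xs, t)
    return VelocityTrace(t=t, v=v, window=window, label=edge.label)


def segment_phases(vt: VelocityTrace, max_candidates: int = 400) -> PhaseSegmentation:
    """Least-squares three-phase segmentation of a velocity trace.

    All (t12, t23) frame pairs are scanned (strided above ``max_candidates``
    frames); ties in residual break toward the earliest t12 (conservative
    phase-1 duration). The phase-1 velocity is the arithmetic mean of the
    velocity over phase 1, independent of the fitted plateau.
    """
    finite = np.isfinite(vt.v) & np.isfinite(vt.t)
    t = vt.t[finite]
    v = vt.v[finite]
    n = t.size
    if n == 0:
        raise ValueError("velocity trace contains no finite samples")
    if n < 20:
        raise ValueError("trace must span at least 20 frames")

    sse_total = float(np.sum(v**2))
    logn = math.log(n)

    def bic(sse: float, k: int) -> float:
        return n * math.log(max(sse, 1e-12) / n) + k * logn

    # nested models
    mean_v = float(v.mean())
    sse_const = float(np.sum((v - mean_v) ** 2))
    best = {"bic": bic(sse_total, 0), "model": "stalled", "sse": sse_total,
            "i": 0, "j": 0}
    c = bic(sse_const, 1)
    if c < best["bic"]:
        best = {"bic": c, "model": "constant", "sse": sse_const,
                "i": n - 1, "j": n - 1}

    stride = max(1, int(math.ceil(n / max_candidates)))
    cand = np.arange(0, n, stride)
    if cand[-1] != n - 1:
        cand = np.append(cand, n - 1)

    p1 = np.concatenate(([0.0], np.cumsum(v)))
    p2 = np.concatenate(([0.0], np.cumsum(v * t)))
    p3 = np.concatenate(([0.0], np.cumsum(t)))
    p4 = np.concatenate(([0.0], np.cumsum(t * t)))

    for i in cand:
        js = cand[cand >= i]
        tj = t[js]
        ti = t[i]
        head = p1[i + 1]          # sum of v over phase 1 (k <= i)
        n1 = i + 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            dt_ij = tj - ti
            a = p1[js] - p1[i + 1]            # sum v over i < k < j
            b = p2[js] - p2[i + 1]            # sum v*t over i < k < j
            s1 = p3[js] - p3[i + 1]
            s2 = p4[js] - p4[i + 1]
            cnt = js - (i + 1)
            sv_m = head + np.where(dt_ij > 0, (tj * a - b) / dt_ij, 0.0)
            sm2 = n1 + np.where(
                dt_ij > 0, (tj**2 * cnt - 2 * tj * s1 + s2) / dt_ij**2, 0.0
            )
            v1 = sv_m / sm2
            sse = sse_total - sv_m**2 / sm2
        k = np.argmin(sse)
        if sse[k] < best["sse"] - 1e-12 and bic(float(sse[k]), 3) < best["bic"]:
            best = {"bic": bic(float(sse[k]), 3), "model": "three_phase",
                    "sse": float(sse[k]), "i": int(i), "j": int(js[k])}

    i, j = best["i"], best["j"]
    if best["model"] == "stalled":
        t12 = t23 = float(t[0])
        v_phase1 = float("nan")
    else:
        t12, t23 = float(t[i]), float(t[j])
        v_phase1 = float(v[: i + 1].mean())
    return PhaseSegmentation(
        t12=t12, t23=t23, v_phase1=v_phase1,
        score=best["sse"], model=best["model"], n=n,
    )


def transition_density_check(event: EventTrace, seg: PhaseSegmentation,
                             tol_s: float = 3.0) -> float:
    """Ratio of the overlap GFP density at t12 to the mean end-tag density.

    The end-tag density is averaged over all frames where the two tags were
    resolved. Returns NaN (undefined) when the tags were never resolved or no
    density measurement exists near t12.
    """
    df = event.frames
    res = df[df["endtags_resolved"]]
    if res.empty:
        return float("nan")
    # per-pixel plateau levels are unbiased by PSF spill at the segment
    # boundaries, unlike the integral densities I/L
    rho_et = float(res["endtag_level"].median())
    if not (rho_et > 0):
        return float("nan")
    # sample the overlap density just before the transition: after t12 the
    # untagged region keeps compressing, which would inflate the ratio
    near = df[(df["t_s"] <= seg.t12) & (df["t_s"] >= seg.t12 - tol_s)]
    if near.empty:
        near = df[np.abs(df["t_s"] - seg.t12) <= tol_s]
    rho = near.loc[near["endtags_resolved"], "untagged_level"].dropna()
    if rho.empty:
        rho = near["rho_untagged"].dropna()
    if rho.empty:
        # merged tags at the transition: the whole overlap is at end-tag
        # density
        dens = (near["I_overlap"] / near["L_overlap"]).dropna()
        if dens.empty:
            return float("nan")
        return float(dens.mean()) / rho_et
    return float(rho.mean()) / rho_et
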