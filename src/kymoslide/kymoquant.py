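"""Kymograph quantification.

Per-frame measurement of a two-channel sliding-event kymograph:

* the microtubule (rhodamine) channel defines the union extent of the two
  filaments and the overlap region (the plateau at twice the single-filament
  intensity);
* the GFP channel defines the end-tags (bright caps at the filament plus-ends
  inside the overlap) and the intensity bookkeeping
  ``I_overlap = I_untagged + I_endtags_in_overlap``.

Edges are localized with sub-pixel precision at half-maximum crossings between
the locally estimated plateaus flanking each edge, which is unbiased for a
PSF-blurred step. All outputs are in nm / seconds / raw intensity units; every
threshold is derived from the data, so measurements are invariant to a global
intensity scale (intensities scale linearly, lengths not at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, gaussian_filter1d

from .kymograph import GFP_CHANNEL, MT_CHANNEL, Kymograph


@dataclass(frozen=True)
class QuantConfig:
    """Tunable thresholds of the quantification (defaults in nm/s/pixels)."""

    smooth_sigma_px: float = 1.0          # light pre-smoothing for localization
    detect_snr: float = 4.0               # structure detection threshold (sigmas)
    endtag_separation_snr: float = 3.0    # plateau bimodality requirement
    min_untagged_px: float = 2.0          # below this, rho_untagged is undefined
    stall_threshold: float = 2.0          # nm/s sustained drift => stalled
    stall_window_s: float = 10.0          # minimum stall duration
    velocity_window: int = 5              # smoothing window (frames) for velocity
    max_gap_frames: int = 10              # tolerated tracking loss


@dataclass
class EdgeTrace:
    """Sub-pixel positions (nm) of one labelled edge over time."""

    frames: np.ndarray
    x: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        if self.frames.size != self.x.size:
            raise ValueError("frames and x must have equal length")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")


@dataclass
class OverlapMeasurement:
    """Geometric and intensity measurements of one kymograph line."""

    frame: int
    ok: bool = False
    reason: str = ""
    extent_lo: float = math.nan
    extent_hi: float = math.nan
    overlap_lo: float = math.nan
    overlap_hi: float = math.nan
    L_overlap: float = math.nan
    L_untagged: float = math.nan
    let1: float = math.nan
    let2: float = math.nan
    I_overlap: float = math.nan
    I_untagged: float = math.nan
    iet1: float = math.nan
    iet2: float = math.nan
    rho_untagged: float = math.nan
    endtags_resolved: bool = False
    #: per-pixel plateau levels from the end-tag segmentation (A.U./px),
    #: unbiased by PSF spill at segment boundaries
    untagged_level: float = math.nan
    endtag_level: float = math.nan
    moving_edge: float = math.nan


@dataclass
class EventTrace:
    """Frame-linked measurements of one sliding event."""

    frames: pd.DataFrame
    edges: dict[str, EdgeTrace]
    L0: float
    L_FO: float
    ml1: float
    ml2: float
    let1: float
    let2: float
    let_frame: int
    t_stall: float
    pixel_size: float
    frame_interval: float
    flags: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def stalled(self) -> bool:
        return math.isfinite(self.L_FO)


# ---------------------------------------------------------------------------
# line-level primitives
# ---------------------------------------------------------------------------

def _background(row: np.ndarray, k: float = 4.0, iters: int = 4) -> float:
    """Iterative off-structure background estimate of one line.

    Seeded from the outermost pixels (the field of view extends beyond the
    structures), then refined as the median of all pixels within ``k`` noise
    standard deviations of the current estimate. The seed avoids latching onto
    a dim structure plateau when background pixels are a minority of the line.
    """
    edge = min(8, max(2, row.size // 16))
    bg = float(np.median(np.concatenate((row[:edge], row[-edge:]))))
    for _ in range(iters):
        noise = math.sqrt(max(bg, 1.0))
        mask = row < bg + k * noise
        if mask.sum() < 5:
            break
        bg = float(np.median(row[mask]))
    return bg


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, idx.size, 2)]


def _cross(sm: np.ndarray, level: float, guess: float, rising: bool,
           window: int) -> float:
    """Sub-pixel crossing of ``level`` nearest ``guess`` (pixel-centre coords)."""
    n = sm.size
    lo = max(0, int(guess) - window)
    hi = min(n - 1, int(guess) + window)
    best, best_d = math.nan, math.inf
    for i in range(lo, hi):
        a, b = sm[i], sm[i + 1]
        if rising:
            hit = a <= level < b or a < level <= b
        else:
            hit = a >= level > b or a > level >= b
        if hit and a != b:
            u = i + (level - a) / (b - a)
            d = abs(u - guess)
            if d < best_d:
                best, best_d = u, d
    return best


def _plateau(sm: np.ndarray, start: int, stop: int) -> float:
    """Median of a short pixel range, clipped to the array."""
    start, stop = max(0, start), min(sm.size, stop)
    if stop <= start:
        return math.nan
    return float(np.median(sm[start:stop]))


def _integrate(values: np.ndarray, lo: float, hi: float) -> float:
    """Integral of a pixel array between fractional cut positions.

    ``values[i]`` is the summed intensity of pixel ``i`` covering the interval
    ``[i, i+1)`` in left-edge pixel coordinates.
    """
    if hi <= lo:
        return 0.0
    lo = max(lo, 0.0)
    hi = min(hi, float(values.size))
    c = np.concatenate(([0.0], np.cumsum(values)))

    def cum(x: float) -> float:
        i = min(int(math.floor(x)), values.size - 1)
        return c[i] + (x - i) * values[i]

    return cum(hi) - cum(lo)


class _Frame:
    """Per-line measurement engine shared by the public entry points."""

    def __init__(self, kymo: Kymograph, frame: int, cfg: QuantConfig):
        self.kymo = kymo
        self.frame = frame
        self.cfg = cfg
        self.px = kymo.pixel_size
        self.sigma_px = max(cfg.smooth_sigma_px, 1e-6)
        self.step_px = math.hypot(cfg.smooth_sigma_px, 1.5)  # blurred-edge width
        self.mt_raw = kymo.mt[frame].astype(float)
        self.gfp_raw = kymo.gfp[frame].astype(float)
        self.mt = gaussian_filter1d(self.mt_raw, self.sigma_px)
        self.gfp = gaussian_filter1d(self.gfp_raw, self.sigma_px)
        self.bg_mt = _background(self.mt_raw)
        self.noise_mt = math.sqrt(max(self.bg_mt, 1.0))
        self.mt_mask = None
        self.bg_gfp = math.nan
        self.noise_gfp = math.nan

    # -- coordinates -------------------------------------------------------
    def to_nm(self, u: float) -> float:
        """Pixel-centre coordinate -> nm."""
        return self.kymo.origin + (u + 0.5) * self.px

    def to_cut(self, x_nm: float) -> float:
        """nm -> left-edge (integration) pixel coordinate."""
        return (x_nm - self.kymo.origin) / self.px

    # -- microtubule channel -------------------------------------------------
    def mt_geometry(self):
        """(extent_lo, extent_hi, overlap_lo, overlap_hi) in nm, or None."""
        cfg = self.cfg
        amp2 = float(np.percentile(self.mt, 98)) - self.bg_mt  # ~ 2x single flux
        if amp2 < cfg.detect_snr * self.noise_mt:
            return None
        # refine: unbiased plateau from the pixels above the provisional
        # threshold (a high percentile alone rides the noise tail)
        for _ in range(2):
            top = self.mt[self.mt > self.bg_mt + 0.75 * amp2]
            if top.size < 4:
                break
            amp2 = float(np.median(top)) - self.bg_mt
        union_level = self.bg_mt + 0.25 * amp2    # half-max of the outer edge
        overlap_level = self.bg_mt + 0.75 * amp2  # half-max between 1x and 2x
        close = np.ones(5, dtype=bool)            # bridge noise-induced gaps
        mask = binary_closing(self.mt > union_level, structure=close)
        runs = _runs(mask)
        if not runs:
            return None
        u0, u1 = max(runs, key=lambda r: r[1] - r[0])
        self.mt_mask = np.zeros(self.mt.size, dtype=bool)
        self.mt_mask[u0:u1] = True
        w = int(math.ceil(4 * self.step_px)) + 2
        e_lo = _cross(self.mt, union_level, u0 - 0.5, True, w)
        e_hi = _cross(self.mt, union_level, u1 - 0.5, False, w)
        sub = self.mt[u0:u1]
        ov_runs = _runs(binary_closing(sub > overlap_level, structure=close))
        if not ov_runs:
            return None
        o0, o1 = max(ov_runs, key=lambda r: r[1] - r[0])
        o0, o1 = o0 + u0, o1 + u0
        # re-estimate the overlap plateau from the run interior (excluding the
        # PSF ramps), so short overlaps do not bias the threshold downward
        inset = int(math.ceil(2 * self.step_px))
        if o1 - inset - (o0 + inset) >= 3:
            amp2 = float(np.median(self.mt[o0 + inset:o1 - inset])) - self.bg_mt
            overlap_level = self.bg_mt + 0.75 * amp2
        v_lo = _cross(self.mt, overlap_level, o0 - 0.5, True, w)
        v_hi = _cross(self.mt, overlap_level, o1 - 0.5, False, w)
        if any(map(math.isnan, (e_lo, e_hi, v_lo, v_hi))):
            return None
        return tuple(self.to_nm(u) for u in (e_lo, e_hi, v_lo, v_hi))

    # -- GFP channel ---------------------------------------------------------
    def gfp_background(self) -> float:
        if self.mt_mask is not None:
            pad = int(math.ceil(3 * self.step_px))
            mask = np.convolve(
                self.mt_mask.astype(float), np.ones(2 * pad + 1), mode="same"
            ) > 0
            off = self.gfp_raw[~mask]
            if off.size >= 8:
                self.bg_gfp = float(np.median(off))
            else:
                self.bg_gfp = _background(self.gfp_raw)
        else:
            self.bg_gfp = _background(self.gfp_raw)
        self.noise_gfp = math.sqrt(max(self.bg_gfp, 1.0))
        return self.bg_gfp


def detect_edges(kymo: Kymograph, channel: int, frame: int,
                 cfg: QuantConfig = QuantConfig()) -> np.ndarray:
    """Outer boundaries (nm) of high-intensity structures in one line.

    Each above-threshold structure contributes its two half-maximum edge
    crossings, localized with linear sub-pixel interpolation against the
    locally estimated plateau; detections closer than one pixel are merged.
    Returns an empty array when nothing rises above the background.
    """
    if not 0 <= frame < kymo.n_frames:
        raise IndexError("frame out of range")
    if channel not in (MT_CHANNEL, GFP_CHANNEL):
        raise ValueError("channel must be 0 (MT) or 1 (GFP)")
    row = kymo.pixels[channel, frame].astype(float)
    sm = gaussian_filter1d(row, max(cfg.smooth_sigma_px, 1e-6))
    bg = _background(row)
    noise = math.sqrt(max(bg, 1.0))
    mask = sm > bg + cfg.detect_snr * noise
    edges: list[float] = []
    w = int(math.ceil(4 * math.hypot(cfg.smooth_sigma_px, 1.5))) + 2
    inset = int(math.ceil(2.5 * math.hypot(cfg.smooth_sigma_px, 1.5)))
    for r0, r1 in _runs(mask):
        if r1 - r0 < 2:
            continue
        hi_l = _plateau(sm, r0 + inset, r0 + inset + 4)
        hi_r = _plateau(sm, r1 - inset - 4, r1 - inset)
        for guess, hi, rising in ((r0 - 0.5, hi_l, True), (r1 - 0.5, hi_r, False)):
            if math.isnan(hi) or hi <= bg:
                hi = float(sm[r0:r1].max())
            u = _cross(sm, 0.5 * (bg + hi), guess, rising, w)
            if not math.isnan(u):
                x = kymo.origin + (u + 0.5) * kymo.pixel_size
                if not edges or abs(x - edges[-1]) > kymo.pixel_size:
                    edges.append(x)
    return np.asarray(sorted(edges))


@dataclass
class EndTagSegmentation:
    let1: float  # immobilized-side (right / plus-end of MT1) end-tag length, nm
    let2: float  # moving-side (left) end-tag length, nm
    inner1: float  # nm position of the immobilized tag's inner boundary
    inner2: float  # nm position of the moving tag's inner boundary
    resolved: bool
    untagged_level: float
    endtag_level: float
    reason: str = ""


def segment_end_tags(
    profile: np.ndarray,
    overlap_bounds: tuple[float, float],
    pixel_size: float,
    origin: float = 0.0,
    noise: float | None = None,
    cfg: QuantConfig = QuantConfig(),
) -> EndTagSegmentation:
    """Segment the two end-tags inside the overlap of a background-subtracted
    GFP line.

    The pixels strictly inside the overlap are split into two intensity
    plateaus (two-means in 1D); if the plateaus are separated by more than
    ``endtag_separation_snr`` times the noise, the end-tag segments are the
    maximal runs above the midpoint threshold that touch the overlap ends, and
    their inner boundaries are localized at the midpoint crossing. Touching or
    merged segments (one run spanning both ends) are reported unresolved.
    """
    profile = np.asarray(profile, dtype=float)
    sm = gaussian_filter1d(profile, max(cfg.smooth_sigma_px, 1e-6))
    lo_nm, hi_nm = overlap_bounds
    step = math.hypot(cfg.smooth_sigma_px, 1.5)
    u_lo = (lo_nm - origin) / pixel_size - 0.5
    u_hi = (hi_nm - origin) / pixel_size - 0.5
    inset = int(math.ceil(1.5 * step))
    i0 = max(0, int(math.ceil(u_lo)) + inset)
    i1 = min(sm.size, int(math.floor(u_hi)) - inset + 1)
    fail = EndTagSegmentation(math.nan, math.nan, math.nan, math.nan, False,
                              math.nan, math.nan)
    if i1 - i0 < 4:
        fail.reason = "overlap_too_short"
        return fail
    vals = sm[i0:i1]
    if noise is None:
        noise = 1.4826 * float(np.median(np.abs(vals - np.median(vals)))) or 1.0

    # two-means split of the overlap intensities
    c_lo, c_hi = float(vals.min()), float(vals.max())
    for _ in range(25):
        mid = 0.5 * (c_lo + c_hi)
        low, high = vals[vals <= mid], vals[vals > mid]
        if low.size == 0 or high.size == 0:
            break
        n_lo, n_hi = float(np.median(low)), float(np.median(high))
        if n_lo == c_lo and n_hi == c_hi:
            break
        c_lo, c_hi = n_lo, n_hi
    low, high = vals[vals <= 0.5 * (c_lo + c_hi)], vals[vals > 0.5 * (c_lo + c_hi)]
    if (
        low.size < 2
        or high.size < 2
        or (c_hi - c_lo) < cfg.endtag_separation_snr * noise
    ):
        fail.untagged_level, fail.endtag_level = c_lo, c_hi
        fail.reason = "no_plateau_separation"
        return fail

    thresh = 0.5 * (c_lo + c_hi)
    mask = sm > thresh
    mask[: i0] = False
    mask[i1:] = False
    runs = _runs(mask)
    if not runs:
        fail.untagged_level, fail.endtag_level = c_lo, c_hi
        fail.reason = "no_segments"
        return fail
    min_tag = max(3, int(math.ceil(2 * step)))  # reject noise runs
    touch_left = [r for r in runs if r[0] <= i0 + 1 and r[1] - r[0] >= min_tag]
    touch_right = [r for r in runs if r[1] >= i1 - 1 and r[1] - r[0] >= min_tag]
    w = int(math.ceil(4 * step)) + 2
    if touch_left and touch_right and touch_left[0] == touch_right[-1]:
        fail.untagged_level, fail.endtag_level = c_lo, c_hi
        fail.reason = "merged"
        return fail

    inner2 = math.nan
    if touch_left:
        u = _cross(sm, thresh, touch_left[0][1] - 0.5, False, w)
        if not math.isnan(u):
            inner2 = origin + (u + 0.5) * pixel_size
    inner1 = math.nan
    if touch_right:
        u = _cross(sm, thresh, touch_right[-1][0] - 0.5, True, w)
        if not math.isnan(u):
            inner1 = origin + (u + 0.5) * pixel_size
    let2 = inner2 - lo_nm if math.isfinite(inner2) else math.nan
    let1 = hi_nm - inner1 if math.isfinite(inner1) else math.nan
    resolved = (
        math.isfinite(let1)
        and math.isfinite(let2)
        and inner2 < inner1  # segments must not cross
    )
    return EndTagSegmentation(
        let1=let1, let2=let2, inner1=inner1, inner2=inner2,
        resolved=resolved, untagged_level=c_lo, endtag_level=c_hi,
        reason="" if resolved else "unresolved",
    )


def measure_frame(kymo: Kymograph, frame: int,
                  cfg: QuantConfig = QuantConfig()) -> OverlapMeasurement:
    """Measure geometry and intensities of one kymograph line.

    Overlap bounds come from the microtubule channel (the region where both
    filament profiles superpose); end-tags and all intensities come from the
    background-subtracted GFP channel. The intensity partition
    ``I_overlap = I_untagged + IET1_in + IET2_in`` holds by construction, the
    three integrals being taken over disjoint sub-intervals of the overlap.
    """
    m = OverlapMeasurement(frame=frame)
    eng = _Frame(kymo, frame, cfg)
    geo = eng.mt_geometry()
    if geo is None:
        m.reason = "no_structure"
        return m
    e_lo, e_hi, o_lo, o_hi = geo
    m.extent_lo, m.extent_hi = e_lo, e_hi
    m.overlap_lo, m.overlap_hi = o_lo, o_hi
    m.L_overlap = o_hi - o_lo
    if m.L_overlap <= 0:
        m.reason = "no_overlap"
        return m

    bg = eng.gfp_background()
    g = eng.gfp_raw - bg
    seg = segment_end_tags(
        g, (o_lo, o_hi), kymo.pixel_size, origin=kymo.origin,
        noise=eng.noise_gfp, cfg=cfg,
    )
    cut = eng.to_cut
    m.I_overlap = _integrate(g, cut(o_lo), cut(o_hi))
    m.untagged_level = seg.untagged_level / kymo.pixel_size
    m.endtag_level = seg.endtag_level / kymo.pixel_size
    if seg.resolved:
        m.endtags_resolved = True
        m.let1, m.let2 = seg.let1, seg.let2
        m.iet2 = _integrate(g, cut(o_lo), cut(seg.inner2))
        m.iet1 = _integrate(g, cut(seg.inner1), cut(o_hi))
        m.I_untagged = _integrate(g, cut(seg.inner2), cut(seg.inner1))
        m.L_untagged = seg.inner1 - seg.inner2
    else:
        # either no end-tags yet (uniform untagged overlap) or merged tags;
        # event-level logic disambiguates using the time course.
        m.I_untagged = m.I_overlap
        m.L_untagged = m.L_overlap
    if m.L_untagged > cfg.min_untagged_px * kymo.pixel_size:
        m.rho_untagged = m.I_untagged / m.L_untagged
    else:
        m.rho_untagged = math.nan

    # moving end-tag outer edge from the GFP channel, guided by the MT overlap
    u_guess = cut(o_lo) - 0.5
    step = eng.step_px
    lo_lvl = _plateau(eng.gfp, int(u_guess - 2.5 * step) - 3, int(u_guess - 2.5 * step) + 1)
    hi_lvl = _plateau(eng.gfp, int(u_guess + 2.5 * step), int(u_guess + 2.5 * step) + 4)
    if math.isfinite(lo_lvl) and math.isfinite(hi_lvl) and hi_lvl > lo_lvl:
        u = _cross(eng.gfp, 0.5 * (lo_lvl + hi_lvl), u_guess,
                   True, int(math.ceil(4 * step)) + 2)
        if not math.isnan(u):
            m.moving_edge = eng.to_nm(u)
    if math.isnan(m.moving_edge):
        m.moving_edge = o_lo  # fall back to the MT-channel overlap edge
    m.ok = True
    return m


# ---------------------------------------------------------------------------
# event tracking
# ---------------------------------------------------------------------------

def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(np.nan_to_num(x), kernel, mode="same")
    den = np.convolve(np.isfinite(x).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return num / den


def track_event(kymo: Kymograph, cfg: QuantConfig = QuantConfig()) -> EventTrace:
    """Measure every line of a kymograph and link the measurements in time.

    The initial overlap L0 is taken from the first measured frame; the stall
    is the earliest time from which the moving edge drifts less than
    ``stall_threshold`` nm/s through the end of the record (sustained at least
    ``stall_window_s``); the final overlap L_FO is the median overlap over the
    stalled portion, and ML1/ML2 are recovered from the union extent and the
    overlap bounds there. End-tag lengths are reported from the last frame on
    which the two tags were resolved.
    """
    ms = [measure_frame(kymo, f, cfg) for f in range(kymo.n_frames)]
    df = pd.DataFrame([vars(m) for m in ms])
    dt = kymo.frame_interval
    df["t_s"] = df["frame"] * dt

    flags: dict = {}
    ok = df["ok"].to_numpy()
    if not ok.any():
        raise ValueError("no frame of this kymograph could be measured")
    gaps = _runs(~ok)
    longest_gap = max((b - a for a, b in gaps), default=0)
    flags["untrackable"] = longest_gap > cfg.max_gap_frames
    flags["n_bad_frames"] = int((~ok).sum())

    first = int(np.flatnonzero(ok)[0])
    L0 = float(df["L_overlap"].iloc[first])

    # moving edge trace (gaps recorded, not interpolated): prefer the bright
    # GFP end-tag edge when the tag exists from the start of the record (a
    # nucleating tag deforms the GFP edge profile). For events that begin
    # untagged, track a shape-stationary MT-channel feature rigidly attached
    # to the moving filament: its far end when that end translates (it sits
    # far from other edges), else the overlap boundary.
    first10 = df.iloc[:10]
    res10 = first10[first10["endtags_resolved"]]
    gfp_from_start = len(res10) >= 8 and bool(
        min(res10["let1"].median(), res10["let2"].median())
        >= 2 * kymo.pixel_size
    )
    if gfp_from_start:
        src, label = "moving_edge", "moving_endtag_outer"
    else:
        far = df.loc[ok, "extent_hi"]
        moved = (
            len(far) >= 20
            and abs(far.iloc[-10:].median() - far.iloc[:10].median())
            > 2 * kymo.pixel_size
        )
        src, label = (("extent_hi", "moving_mt_far_end") if moved
                      else ("overlap_lo", "overlap_left_mt"))
    x = df[src].to_numpy(dtype=float)
    x[~ok] = np.nan
    # temporal consistency: a position far off the local median is a gross
    # per-frame localization failure -> recorded as a gap, not interpolated
    med = pd.Series(x).rolling(7, center=True, min_periods=3).median().to_numpy()
    outlier = np.isfinite(x) & np.isfinite(med) & (
        np.abs(x - med) > 4 * kymo.pixel_size)
    x[outlier] = np.nan
    flags["n_edge_outliers"] = int(outlier.sum())
    edge = EdgeTrace(
        frames=np.flatnonzero(np.isfinite(x)), x=x[np.isfinite(x)], label=label,
    )

    # stall: earliest index from which total drift stays below threshold
    xs = _rolling_mean(x, cfg.velocity_window)
    n = xs.size
    w_frames = max(2, int(round(cfg.stall_window_s / dt)))
    fin = np.isfinite(xs)
    t_stall, stall_idx = math.nan, None
    if fin.any():
        last = int(np.flatnonzero(fin)[-1])
        x_end = xs[last]
        for i in range(n - w_frames):
            if not fin[i]:
                continue
            span = (last - i) * dt
            if span < cfg.stall_window_s:
                break
            j_fwd = min(i + w_frames, last)
            local_ok = (
                fin[j_fwd]
                and abs(xs[j_fwd] - xs[i]) / max((j_fwd - i) * dt, dt)
                < cfg.stall_threshold
            )
            if local_ok and abs(x_end - xs[i]) / span < cfg.stall_threshold:
                # require the drift bound to hold from i to the end, sampled
                # at window resolution, so a mid-record pause does not trigger
                later = np.flatnonzero(fin[i:last + 1])[::w_frames] + i
                if all(
                    abs(x_end - xs[j]) / max((last - j) * dt, dt)
                    < 2 * cfg.stall_threshold
                    for j in later[:-1]
                ):
                    t_stall, stall_idx = i * dt, i
                    break

    L_FO = math.nan
    ml1 = ml2 = math.nan
    if stall_idx is not None:
        # average over the tail of the stalled portion, where residual creep
        # has certainly ceased
        tail = max(stall_idx, n - max(w_frames, (n - stall_idx) // 2))
        sl = df.iloc[tail:]
        sl = sl[sl["ok"]]
        L_FO = float(sl["L_overlap"].median())
        ml1 = float((sl["overlap_hi"] - sl["extent_lo"]).median())
        ml2 = float((sl["extent_hi"] - sl["overlap_lo"]).median())
    else:
        sl = df[df["ok"]].iloc[-10:]
        ml1 = float((sl["overlap_hi"] - sl["extent_lo"]).median())
        ml2 = float((sl["extent_hi"] - sl["overlap_lo"]).median())
        flags["no_stall"] = True

    res = df["endtags_resolved"].to_numpy()
    let1 = let2 = math.nan
    let_frame = -1
    if res.any():
        # median over the last resolved frames: robust against spurious
        # detections right at the resolution limit
        idx = np.flatnonzero(res)[-5:]
        let_frame = int(idx[-1])
        let1 = float(df["let1"].iloc[idx].median())
        let2 = float(df["let2"].iloc[idx].median())

    cols = ["frame", "t_s", "extent_lo", "extent_hi", "overlap_lo",
            "overlap_hi", "L_overlap", "L_untagged", "let1", "let2",
            "I_overlap", "I_untagged", "iet1", "iet2", "rho_untagged",
            "untagged_level", "endtag_level", "endtags_resolved",
            "moving_edge", "ok", "reason"]
    return EventTrace(
        frames=df[cols],
        edges={"moving": edge},
        L0=L0,
        L_FO=L_FO,
        ml1=ml1,
        ml2=ml2,
        let1=let1,
        let2=let2,
        let_frame=let_frame,
        t_stall=t_stall,
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        flags=flags,
        meta=dict(kymo.meta),
    )
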