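"""Synthetic sliding events and kymograph rendering.

This module generates ground-truth trajectories of a pair of antiparallel,
crosslinked microtubules sliding under a motor/crosslinker ensemble
(PRC1-Kif4A-like), and renders them as noisy two-channel TIRF kymographs so
that the quantification pipeline can be validated end-to-end without
experimental data.

Geometry (1D axis, nm):

* the immobilized microtubule spans ``[0, ML1]`` with its plus-end at ``ML1``;
* the moving microtubule spans ``[s, s + ML2]`` with its plus-end at ``s``;
* plus-end directed stepping on the immobilized lattice transports the moving
  microtubule toward the immobilized plus-end, i.e. sliding increases ``s``.

Mechanics:

* end-tags (dense protein caps) grow at the plus-end of each microtubule at a
  constant rate until they reach a length proportional to the microtubule
  length (``endtag_fraction * ML``);
* the number of sliding-competent complexes is set by the *initial* untagged
  overlap, ``N = a * L_untagged(0) / delta``; molecules recruited at assay
  start are conserved while the overlap shrinks (their density rises), so the
  base velocity ``v = v0 * (1 - (1 - S)**N)`` is constant during phase 1;
* when the gap between the inner boundaries of the two end-tags falls below a
  slowdown scale ``w`` the velocity is attenuated by ``sqrt(gap / w)``, which
  makes the velocity decay linearly in time and close the gap in finite time
  (phase 2);
* sliding halts permanently when the end-tag inner boundaries meet (phase 3),
  so the final overlap equals the sum of the two end-tag lengths at stall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kymograph import Kymograph

try:  # SciPy is a hard dependency of the package; guard only for doc tools
    from scipy.ndimage import gaussian_filter1d
except ImportError:  # pragma: no cover
    gaussian_filter1d = None


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Mechanical parameters of one simulated sliding event (lengths in nm).

    ``v0`` is the maximal (unloaded-ensemble) sliding velocity in nm/s,
    ``sliding_efficiency`` the probability S that a complex is in a dual-bound,
    sliding-competent configuration, ``occupancy`` the fractional occupancy a
    of sliding-competent complexes on the lattice and ``delta`` the 8 nm
    binding-site length, so that ``N = a * L / delta``.
    """

    ml1: float
    ml2: float
    s0: float
    v0: float = 58.0
    sliding_efficiency: float = 0.095
    occupancy: float = 0.05
    delta: float = 8.0
    endtag_fraction: float = 0.3
    endtag_growth_rate: float = 20.0
    #: start with end-tags already at their length-scaled plateau, as on
    #: microtubules that carried end-tags before the pair was crosslinked.
    endtags_preformed: bool = False
    slowdown_width: float = 500.0
    #: if set, phase-2 attenuation starts when the modelled untagged protein
    #: density reaches this fraction of the end-tag density instead of at a
    #: fixed gap; ``initial_density_ratio`` is rho_untagged(0)/rho_endtag.
    slowdown_density_fraction: float | None = None
    initial_density_ratio: float = 0.4
    duration: float = 450.0
    dt: float = 1.0 / 3.0
    #: keep recording this many seconds after the stall (0 => stop at stall).
    record_after_stall: float = 40.0

    def __post_init__(self) -> None:
        if not (self.ml1 > 0 and self.ml2 > 0):
            raise ValueError("microtubule lengths must be positive")
        if not (self.v0 > 0 and self.duration > 0 and self.dt > 0):
            raise ValueError("v0, duration and dt must be positive")
        if self.dt >= self.duration:
            raise ValueError("time step dt must be smaller than duration")
        if not (0.0 <= self.sliding_efficiency <= 1.0):
            raise ValueError("sliding efficiency S must lie in [0, 1]")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy a must lie in (0, 1]")
        if self.delta <= 0:
            raise ValueError("binding-site length delta must be positive")
        if not (0.0 <= self.endtag_fraction < 0.5):
            raise ValueError("endtag_fraction must lie in [0, 0.5)")
        if self.endtag_growth_rate < 0:
            raise ValueError("endtag_growth_rate must be non-negative")
        if self.slowdown_width <= 0:
            raise ValueError("slowdown_width must be positive")
        if self.initial_overlap <= 0:
            raise ValueError("microtubules must overlap initially")

    @property
    def initial_overlap(self) -> float:
        """Initial overlap length min(ML1, s0+ML2) - max(0, s0) in nm."""
        return min(self.ml1, self.s0 + self.ml2) - max(0.0, self.s0)

    @property
    def initial_endtags(self) -> tuple[float, float]:
        """End-tag lengths at t = 0 (nm)."""
        if self.endtags_preformed:
            return (self.endtag_fraction * self.ml1, self.endtag_fraction * self.ml2)
        return (0.0, 0.0)

    @property
    def initial_untagged(self) -> float:
        """Untagged-overlap length at t = 0 (nm)."""
        let1, let2 = self.initial_endtags
        return _geometry(self, self.s0, let1, let2)[1]

    @property
    def n_complexes(self) -> float:
        """Number of sliding-competent complexes, set by the initial untagged
        overlap (molecules recruited at assay start are conserved)."""
        return self.occupancy * self.initial_untagged / self.delta

    @property
    def base_velocity(self) -> float:
        """Phase-1 velocity v0 * (1 - (1 - S)**N) in nm/s."""
        from .overlap_model import ensemble_velocity

        return ensemble_velocity(self.v0, self.sliding_efficiency, self.n_complexes)


@dataclass(frozen=True)
class OpticsParams:
    """Imaging model for rendering (TIRF + sCMOS-like, Poisson statistics).

    Fluxes are photons (A.U.) per nm of structure: ``rho_single`` on single
    (non-overlapped) microtubule regions, ``rho_untagged`` on the untagged
    overlap at t = 0 and ``rho_endtag`` on end-tags in the GFP channel;
    ``mt_flux`` per microtubule in the rhodamine channel. The pixel value is
    the integral of the PSF-blurred flux over the pixel plus a uniform
    ``background``, with Poisson noise.
    """

    pixel_size: float = 100.0
    frame_interval: float = 1.0 / 3.0
    psf_sigma: float = 150.0
    rho_single: float = 0.7
    rho_untagged: float = 3.5
    rho_endtag: float = 8.75
    mt_flux: float = 5.0
    background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.psf_sigma < 0 or self.background < 0:
            raise ValueError("psf_sigma and background must be non-negative")
        for name in ("rho_single", "rho_untagged", "rho_endtag", "mt_flux"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rho_untagged > 0 and not (
            self.rho_single < self.rho_untagged < self.rho_endtag
        ):
            raise ValueError(
                "fluxes must satisfy rho_single < rho_untagged < rho_endtag"
            )

    def untagged_snr(self) -> float:
        """Per-pixel SNR of the untagged-overlap plateau in the GFP channel."""
        plateau = self.rho_untagged * self.pixel_size
        if plateau == 0:
            return 0.0
        return plateau / math.sqrt(plateau + self.background)

    def scaled_to_snr(self, snr: float) -> "OpticsParams":
        """Rescale fluxes so both channels have the requested per-pixel SNR.

        GFP fluxes are scaled together so the untagged-overlap plateau has
        SNR ``snr``; the microtubule flux is scaled independently so the
        single-filament plateau has the same SNR (signal over Poisson noise
        including background).
        """
        if snr <= 0:
            raise ValueError("snr must be positive")
        b = self.background
        # solve x / sqrt(x + b) = snr for the plateau x
        x = 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * b))
        k_gfp = x / (self.rho_untagged * self.pixel_size)
        k_mt = x / (self.mt_flux * self.pixel_size)
        return replace(
            self,
            rho_single=self.rho_single * k_gfp,
            rho_untagged=self.rho_untagged * k_gfp,
            rho_endtag=self.rho_endtag * k_gfp,
            mt_flux=self.mt_flux * k_mt,
        )


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthTrajectory:
    """Per-frame ground truth of one simulated event (lengths nm, times s)."""

    t: np.ndarray
    s: np.ndarray
    overlap: np.ndarray
    untagged: np.ndarray
    let1: np.ndarray
    let2: np.ndarray
    v: np.ndarray
    phase: np.ndarray
    final_overlap: float
    t_stall: float
    params: SimulationParams

    @property
    def stalled(self) -> bool:
        return np.isfinite(self.final_overlap)

    @property
    def n_frames(self) -> int:
        return self.t.size

    def phase1_velocity(self) -> float:
        """Mean true velocity over phase-1 frames (nm/s)."""
        mask = self.phase == 1
        if not mask.any():
            return float("nan")
        return float(self.v[mask].mean())

    def changepoints(self) -> tuple[float, float]:
        """True (t12, t23) in seconds; record end if a phase never occurs."""
        t12 = self.t[self.phase >= 2]
        t23 = self.t[self.phase == 3]
        end = float(self.t[-1])
        return (
            float(t12[0]) if t12.size else end,
            float(t23[0]) if t23.size else end,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "s_nm": self.s,
                "L_overlap_nm": self.overlap,
                "LET1_nm": self.let1,
                "LET2_nm": self.let2,
                "v_nm_per_s": self.v,
                "phase": self.phase,
            }
        )


def _interval_length(lo: float, hi: float) -> float:
    return max(0.0, hi - lo)


def _geometry(p: SimulationParams, s: float, let1: float, let2: float):
    """Overlap and untagged-overlap intervals for one state."""
    ov_lo = max(0.0, s)
    ov_hi = min(p.ml1, s + p.ml2)
    overlap = _interval_length(ov_lo, ov_hi)
    # untagged region: overlap minus the two end-tag caps
    un_lo = max(ov_lo, s + let2)
    un_hi = min(ov_hi, p.ml1 - let1)
    untagged = _interval_length(un_lo, un_hi)
    return overlap, untagged


def simulate_pair(params: SimulationParams) -> GroundTruthTrajectory:
    """Integrate one sliding event on a regular grid of step ``dt``.

    The inner-boundary gap ``g = (ML1 - LET1) - (s + LET2)`` closes through
    sliding and end-tag growth; when a step would make it negative the state is
    advanced to the exact meeting point (linear sub-step), sliding halts
    permanently and end-tag growth stops (no free lattice sites remain), so
    ``final_overlap == LET1 + LET2`` holds exactly at stall.
    """
    p = params
    let1, let2 = p.initial_endtags
    lu0 = _geometry(p, p.s0, let1, let2)[1]
    v_base = p.base_velocity
    if p.slowdown_density_fraction is not None:
        if not (0.0 < p.slowdown_density_fraction <= 1.0):
            raise ValueError("slowdown_density_fraction must lie in (0, 1]")
        w = min(lu0, p.initial_density_ratio * lu0 / p.slowdown_density_fraction)
    else:
        w = p.slowdown_width

    let1_cap = p.endtag_fraction * p.ml1
    let2_cap = p.endtag_fraction * p.ml2

    n_steps = int(math.ceil(p.duration / p.dt))
    t_arr, s_arr, ov_arr, un_arr = [], [], [], []
    l1_arr, l2_arr, v_arr, ph_arr = [], [], [], []

    s = float(p.s0)
    stalled = False
    t_stall = float("nan")
    final_overlap = float("nan")

    for k in range(n_steps + 1):
        t = k * p.dt
        gap = (p.ml1 - let1) - (s + let2)
        if stalled:
            v = 0.0
            phase = 3
        else:
            factor = math.sqrt(min(1.0, max(0.0, gap / w)))
            v = v_base * factor
            phase = 1 if factor >= 1.0 else 2

        overlap, untagged = _geometry(p, s, let1, let2)
        t_arr.append(t)
        s_arr.append(s)
        ov_arr.append(overlap)
        un_arr.append(untagged)
        l1_arr.append(let1)
        l2_arr.append(let2)
        v_arr.append(v)
        ph_arr.append(phase)

        if stalled and t - t_stall >= p.record_after_stall:
            break
        if stalled:
            continue

        # advance one step
        s_new = s + v * p.dt
        let1_new = min(let1 + p.endtag_growth_rate * p.dt, let1_cap)
        let2_new = min(let2 + p.endtag_growth_rate * p.dt, let2_cap)
        gap_new = (p.ml1 - let1_new) - (s_new + let2_new)
        if gap_new <= 0.0 and gap > 0.0:
            # sub-step to the exact collision (state is linear in alpha)
            alpha = gap / (gap - gap_new)
            let1 = min(let1 + alpha * p.endtag_growth_rate * p.dt, let1_cap)
            let2 = min(let2 + alpha * p.endtag_growth_rate * p.dt, let2_cap)
            s = (p.ml1 - let1) - let2  # gap exactly zero
            stalled = True
            t_stall = t + alpha * p.dt
            final_overlap = let1 + let2
        elif gap_new <= 0.0:
            # degenerate: started at (or past) collision
            s = (p.ml1 - let1) - let2
            stalled = True
            t_stall = t
            final_overlap = let1 + let2
        else:
            s, let1, let2 = s_new, let1_new, let2_new

    return GroundTruthTrajectory(
        t=np.asarray(t_arr),
        s=np.asarray(s_arr),
        overlap=np.asarray(ov_arr),
        untagged=np.asarray(un_arr),
        let1=np.asarray(l1_arr),
        let2=np.asarray(l2_arr),
        v=np.asarray(v_arr),
        phase=np.asarray(ph_arr, dtype=int),
        final_overlap=final_overlap,
        t_stall=t_stall,
        params=p,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint(flux: np.ndarray, cell: float, origin: float, lo: float, hi: float,
           value: float, additive: bool = False) -> None:
    """Set (or add) ``value`` flux on the interval [lo, hi) of a fine grid."""
    if hi <= lo:
        return
    i0 = max(0, int(math.floor((lo - origin) / cell)))
    i1 = min(flux.size, int(math.ceil((hi - origin) / cell)))
    if i1 <= i0:
        return
    if additive:
        flux[i0:i1] += value
    else:
        flux[i0:i1] = value


def render_kymograph(
    traj: GroundTruthTrajectory,
    optics: OpticsParams,
    *,
    margin: float = 2000.0,
    noise: bool = True,
    rng: np.random.Generator | None = None,
    event_id: str | None = None,
) -> Kymograph:
    """Render a trajectory as a two-channel kymograph.

    The untagged-overlap GFP flux follows the molecule-conservation model:
    the density rises as ``rho_untagged * L_untagged(0) / L_untagged(t)``,
    capped at the end-tag density (the lattice cannot be over-filled). With
    ``noise=False`` the noiseless Poisson means (including background) are
    returned, which is the expected value of the noisy image.
    """
    p = traj.params
    if optics.pixel_size > min(p.ml1, p.ml2):
        raise ValueError(
            "pixel size exceeds the smallest structure to render; "
            "decrease pixel_size or use longer microtubules"
        )
    if abs(optics.frame_interval - p.dt) > 1e-9:
        raise ValueError("optics.frame_interval must match the simulation dt")

    x_min = min(0.0, float(traj.s.min())) - margin
    x_max = max(p.ml1, float(traj.s.max()) + p.ml2) + margin
    n_px = int(math.ceil((x_max - x_min) / optics.pixel_size))
    oversample = max(1, int(round(optics.pixel_size / 25.0)))
    cell = optics.pixel_size / oversample
    n_fine = n_px * oversample
    sigma_cells = optics.psf_sigma / cell

    lu0 = traj.untagged[0] if traj.untagged.size else 0.0
    img = np.zeros((2, traj.n_frames, n_px))

    for k in range(traj.n_frames):
        s, let1, let2 = traj.s[k], traj.let1[k], traj.let2[k]
        lu = traj.untagged[k]

        mt = np.zeros(n_fine)
        _paint(mt, cell, x_min, 0.0, p.ml1, optics.mt_flux, additive=True)
        _paint(mt, cell, x_min, s, s + p.ml2, optics.mt_flux, additive=True)

        gfp = np.zeros(n_fine)
        _paint(gfp, cell, x_min, 0.0, p.ml1, optics.rho_single)
        _paint(gfp, cell, x_min, s, s + p.ml2, optics.rho_single)
        if lu > 0 and lu0 > 0:
            rho_u = min(optics.rho_endtag, optics.rho_untagged * lu0 / lu)
            un_lo = max(max(0.0, s), s + let2)
            un_hi = min(min(p.ml1, s + p.ml2), p.ml1 - let1)
            _paint(gfp, cell, x_min, un_lo, un_hi, rho_u)
        if let1 > 0:
            _paint(gfp, cell, x_min, p.ml1 - let1, p.ml1, optics.rho_endtag)
        if let2 > 0:
            _paint(gfp, cell, x_min, s, s + let2, optics.rho_endtag)

        for c, prof in ((0, mt), (1, gfp)):
            if sigma_cells > 0:
                prof = gaussian_filter1d(prof, sigma_cells, mode="constant")
            counts = prof.reshape(n_px, oversample).sum(axis=1) * cell
            img[c, k] = counts + optics.background

    if noise:
        if rng is None:
            rng = np.random.default_rng(optics.seed)
        img = rng.poisson(img).astype(float)

    meta = {"event_id": event_id, "margin_nm": margin}
    return Kymograph(
        pixels=img,
        pixel_size=optics.pixel_size,
        frame_interval=optics.frame_interval,
        origin=x_min,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """Distributions defining one experimental condition.

    Microtubule lengths and the initial overlap are drawn uniformly from the
    given ranges (nm); the per-event untagged GFP density is drawn from a
    truncated normal to emulate event-to-event variation in motor recruitment.
    The moving microtubule is placed so that its plus-end starts ``overlap``
    nm short of the immobilized plus-end (s0 = ML1 - L0), the configuration in
    which the overlap shrinks from the first frame.
    """

    name: str = "condition"
    ml1_range: tuple[float, float] = (4000.0, 10000.0)
    ml2_range: tuple[float, float] = (4000.0, 10000.0)
    overlap_range: tuple[float, float] = (2500.0, 5000.0)
    v0: float = 58.0
    sliding_efficiency: float = 0.095
    occupancy: float = 0.05
    delta: float = 8.0
    endtag_fraction: float = 0.3
    endtag_growth_rate: float = 20.0
    endtags_preformed: bool = False
    slowdown_width: float = 500.0
    slowdown_density_fraction: float | None = None
    rho_untagged_mean: float = 3.5
    rho_untagged_sd: float = 1.7
    #: rescale fluxes per event so the untagged plateau has this SNR (None
    #: keeps absolute fluxes, required when densities are the measurand).
    snr: float | None = None
    duration: float = 450.0
    dt: float = 1.0 / 3.0
    optics: OpticsParams = field(default_factory=OpticsParams)
    #: require the initial overlap to exceed the saturated end-tag sum, so
    #: end-tags are fully grown before they collide.
    require_saturated_endtags: bool = False
    max_tries: int = 1000


@dataclass
class SimulatedEvent:
    event_id: str
    params: SimulationParams
    optics: OpticsParams
    traj: GroundTruthTrajectory
    kymo: Kymograph | None


def _sample_params(cond: ConditionSpec, rng: np.random.Generator) -> SimulationParams:
    for _ in range(cond.max_tries):
        ml1 = rng.uniform(*cond.ml1_range)
        ml2 = rng.uniform(*cond.ml2_range)
        l0 = rng.uniform(*cond.overlap_range)
        if l0 > min(ml1, ml2) - 200.0:
            continue
        if (cond.require_saturated_endtags or cond.endtags_preformed) and (
            l0 < cond.endtag_fraction * (ml1 + ml2) + 800.0
        ):
            continue
        return SimulationParams(
            ml1=ml1,
            ml2=ml2,
            s0=ml1 - l0,
            v0=cond.v0,
            sliding_efficiency=cond.sliding_efficiency,
            occupancy=cond.occupancy,
            delta=cond.delta,
            endtag_fraction=cond.endtag_fraction,
            endtag_growth_rate=cond.endtag_growth_rate,
            endtags_preformed=cond.endtags_preformed,
            slowdown_width=cond.slowdown_width,
            slowdown_density_fraction=cond.slowdown_density_fraction,
            duration=cond.duration,
            dt=cond.dt,
        )
    raise RuntimeError(
        f"condition {cond.name!r}: could not sample a geometrically valid "
        f"event in {cond.max_tries} tries (degenerate distributions?)"
    )


def _sample_optics(cond: ConditionSpec, rng: np.random.Generator, seed: int) -> OpticsParams:
    rho_u = -1.0
    for _ in range(cond.max_tries):
        rho_u = rng.normal(cond.rho_untagged_mean, cond.rho_untagged_sd)
        if rho_u > 0.5:
            break
    optics = replace(
        cond.optics,
        rho_untagged=rho_u,
        rho_single=rho_u / 5.0,
        rho_endtag=2.5 * rho_u,
        frame_interval=cond.dt,
        seed=seed,
    )
    if cond.snr is not None:
        optics = optics.scaled_to_snr(cond.snr)
    return optics


def simulate_ensemble(
    cond: ConditionSpec,
    n: int,
    seed: int,
    *,
    render: bool = True,
) -> list[SimulatedEvent]:
    """Simulate ``n`` independent events of one condition, reproducibly.

    Every stochastic draw (geometry, per-event density, rendering noise)
    derives from ``seed`` through one `numpy.random.SeedSequence` spawn per
    event, so ensembles are identical under repeated seeds and individual
    events can be regenerated independently.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    events: list[SimulatedEvent] = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        params = _sample_params(cond, rng)
        optics = _sample_optics(cond, rng, seed=int(ss.generate_state(1)[0] % (2**31)))
        traj = simulate_pair(params)
        kymo = None
        if render:
            kymo = render_kymograph(
                traj, optics, rng=rng, event_id=f"{cond.name}_{i:03d}"
            )
            kymo.meta["condition"] = cond.name
        events.append(
            SimulatedEvent(
                event_id=f"{cond.name}_{i:03d}",
                params=params,
                optics=optics,
                traj=traj,
                kymo=kymo,
            )
        )
    return events


def truth_table(events: Sequence[SimulatedEvent]) -> pd.DataFrame:
    """Per-event ground-truth summary of an ensemble."""
    rows = []
    for ev in events:
        tr, p = ev.traj, ev.params
        t12, t23 = tr.changepoints()
        stall_idx = np.flatnonzero(tr.phase == 3)
        k = stall_idx[0] if stall_idx.size else -1
        rows.append(
            {
                "event_id": ev.event_id,
                "ml1_nm": p.ml1,
                "ml2_nm": p.ml2,
                "initial_overlap_nm": p.initial_overlap,
                "v_phase1_nm_s": tr.phase1_velocity(),
                "final_overlap_nm": tr.final_overlap,
                "let1_nm": tr.let1[k],
                "let2_nm": tr.let2[k],
                "t12_s": t12,
                "t23_s": t23,
                "stalled": tr.stalled,
                "rho_untagged": ev.optics.rho_untagged,
            }
        )
    return pd.DataFrame(rows)
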