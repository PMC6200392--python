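# Methods

## The mechanical model

One spatial axis, lengths in nm, time in s. The immobilized microtubule spans
`[0, ML1]` with its plus-end at `ML1`; the moving microtubule spans
`[s, s + ML2]` with its plus-end at `s`. Plus-end-directed stepping of
motor-crosslinker complexes on the immobilized lattice transports the moving
filament toward the immobilized plus-end, so sliding increases `s`. The
overlap is `[max(0, s), min(ML1, s + ML2)]`; the untagged overlap is the part
of it not covered by an end-tag.

**Ensemble velocity.** A complex contributes to sliding only while it is in
its dual-bound ("sliding-competent") configuration, which it occupies with
probability `S` (the sliding efficiency, the complex-level analogue of a
motor duty ratio). With `N` complexes available, the filament moves whenever
at least one is engaged:

    v = v0 * (1 - (1 - S)**N),        N = a * L_untagged / delta,

with `delta = 8 nm` per binding site and `a` the fractional occupancy of
sliding-competent complexes. `N` is treated as continuous (it is estimated
from lengths and intensities, never counted).

**Molecule conservation.** `N` is evaluated once, from the *initial* untagged
overlap. The complexes recruited at assay start stay associated with the
shrinking overlap - their linear density rises - so the phase-1 velocity is
constant even while the overlap shortens. (Tying `N` to the instantaneous
untagged length instead would make the velocity fall continuously from the
first frame, contradicting the constant-velocity phase that motivates the
model.)

**End-tags.** Each plus-end carries an end-tag that grows at
`endtag_growth_rate` (default 20 nm/s) to a plateau proportional to its
filament, `LET_i = endtag_fraction * ML_i`. The length-proportional plateau
is taken as given (it is an input of this model, not a prediction).
`endtags_preformed=True` starts the tags at their plateau, the appropriate
regime for filaments that carried end-tags before crosslinking; it is also
the regime in which the final overlap reflects *saturated* tags.

**Slowdown and stall.** Let `g = (ML1 - LET1) - (s + LET2)` be the gap
between the inner boundaries of the two tags. For `g < w` (slowdown scale
`w = 500 nm` by default) the velocity is attenuated by `sqrt(g / w)`. The
functional form of the slowdown is not experimentally constrained; the
square-root ramp was chosen because (i) it is a local, single-parameter,
gap-dependent rule, and (ii) with `dg/dt = -v` it makes the velocity decay
*linearly in time* and reach zero in finite time `2w/v1` - the gap closes
exactly, matching the piecewise-linear three-phase description and making the
stall well-defined. (A ramp linear in the gap would close the gap only
asymptotically.) Alternatively, `slowdown_density_fraction = q` starts the
attenuation when the modelled untagged protein density reaches a fraction `q`
of the end-tag density. When a step would overshoot the collision, the state
is advanced to the exact meeting point by a linear sub-step, sliding halts
permanently and tag growth stops (no free sites remain), so
`L_FO = LET1 + LET2` holds exactly at stall.

**Phases.** Phase 1: attenuation factor = 1. Phase 2: 0 < factor < 1.
Phase 3: stalled. Phase labels are non-decreasing in time.

## The imaging model

Each frame is a 1-D line. Microtubule channel: `mt_flux` (A.U./nm) per
filament, additive in the overlap. GFP channel: `rho_single` on
single-filament regions, `rho_endtag` on end-tags, and on the untagged
overlap the conservation density `min(rho_endtag, rho_untagged *
L_untagged(0) / L_untagged(t))` - the total untagged intensity falls while
its density rises, capped at the end-tag density (the lattice cannot be
overfilled). Profiles are convolved with a Gaussian PSF (sigma 150 nm),
integrated over 100-nm pixels (25-nm sub-sampling), offset by a uniform
background (100 counts) and Poisson-sampled. A single integer seed drives
all randomness. `OpticsParams.scaled_to_snr(snr)` rescales the GFP fluxes so
the untagged plateau has the requested per-pixel SNR
(`plateau / sqrt(plateau + background)`) and independently rescales the
microtubule flux to the same SNR on the single-filament plateau; without the
per-channel split, a bright GFP event would starve the geometry channel.

Defaults (pixel 100 nm, 3 frames/s, PSF sigma 150 nm, background 100) are
typical TIRF/sCMOS scales; all are configurable.

## Calibrated study conditions

`conditions.py` fixes two named conditions, calibrated analytically (not by
iterating on test results):

- **low_crosslinker**: `v0 = 58 nm/s`, `S = 0.095`, `a = 0.05`. Chosen so
  that (i) the mean phase-1 velocity over initial overlaps 0.8-5 um is
  ~46 nm/s and (ii) fitting the saturating relation
  `v = v0 L / (L + K_L)` to ensemble-law data over that range returns
  `K_L ~ 1.7 um` - the value for which the efficiency calculation spans
  S ~ 0.3 (at a = 1%) down to ~0.03 (at a = 10%). Untagged density
  3.5 +/- 1.7 A.U./nm across events; end-tag fraction 0.3.
- **high_crosslinker**: more crosslinker recruits more motor (density
  6.5 +/- 1.9 A.U./nm, `a = 0.10`) but crowds the lattice; `S = 0.0059`
  gives a mean velocity of ~11 nm/s over the same overlap range. End-tag
  fraction 0.4.

Note the fitted `K_L` is *not* the designed half-max of the ensemble law:
the hyperbolic form approaches saturation more slowly than the
`1-(1-S)^N` law, so the fit compensates with a larger `v0` and `K_L`. The
calibration therefore targets the *fitted* `K_L`, since that is the quantity
entering the efficiency formula.

The single-molecule intensity calibration is fixed at 350 A.U. per
GFP-labelled motor, so the low-crosslinker untagged density of 3.5 A.U./nm
corresponds to ~10 molecules per micrometre of overlap
(`ensemble_stats.molecules_per_micron`).

Two auxiliary conditions serve validation: `roadblock_saturated` (pre-formed
0.4-fraction tags; the regime of the roadblock identity) and `roundtrip`
(pre-formed 0.3-fraction tags with a 1.5-3.5 um untagged runway so all three
phases occur in every record).

## Quantification

Per line: the background is the median of off-structure pixels, seeded from
the outermost pixels of the field (a percentile seed latches onto dim
structure plateaus when background pixels are a minority). Structures are
thresholded (with morphological closing over <=5-px gaps), and every edge is
localized at the half-maximum between the plateaus flanking it, with linear
sub-pixel interpolation - unbiased for a PSF-blurred step. The overlap is
the region above 1.5x the single-filament plateau in the microtubule
channel; the plateau itself is re-estimated from the interior of the overlap
run so short overlaps do not bias the threshold. Microtubule lengths follow
from the union extent and the overlap bounds at stall
(`ML1 = overlap_hi - extent_lo`, `ML2 = extent_hi - overlap_lo`).

End-tags are segmented in the background-subtracted GFP channel inside the
overlap: a 1-D two-means split of the interior pixels yields the untagged and
end-tag plateau levels; if they separate by more than 3x the noise, the tag
segments are the maximal runs above the midpoint threshold touching the
overlap ends (each at least two blur widths long, rejecting noise runs), and
their inner boundaries are localized at the midpoint crossing. Touching or
merged segments are reported unresolved; event-level tag lengths are the
median over the last five resolved frames. The intensity partition
`I_overlap = I_untagged + IET1_in + IET2_in` holds by construction (the three
integrals cover disjoint sub-intervals of the overlap, with fractional
pixels at sub-pixel boundaries).

**Moving-edge velocimetry.** When the end-tags exist from the first frames,
the tracked edge is the bright outer edge of the moving end-tag in the GFP
channel. When the record starts untagged, a *nucleating* tag continuously
deforms that edge profile and injects a spurious apparent velocity; the
tracker then uses a shape-stationary microtubule-channel feature rigidly
attached to the moving filament - its far end, which translates with the same
`ds/dt` and sits far from all other edges (falling back to the overlap
boundary if the far end does not translate). Positions deviating more than
4 px from a 7-frame rolling median are recorded as gaps, never interpolated.

**Stall and final overlap.** The stall is the earliest time from which both
the local forward drift (over the 10-s stall window) and the drift to the end
of the record stay below 2 nm/s; `L_FO`, `ML1`, `ML2` are medians over the
tail of the stalled portion. The stall criterion (2 nm/s over >= 10 s) is a
package choice; the underlying observation is only that stalls are permanent.

**Velocity and phases.** The instantaneous velocity is the gradient of the
smoothed edge position; smoothing is an order-1 Savitzky-Golay filter -
identical to a centered moving average (default window 5 frames, ~1.7 s at
3 frames/s) in the interior but trend-preserving at the boundaries, where a
plain windowed mean biases the first and last half-window of a moving edge.
The three-phase model (constant `v1`, continuous linear decay to 0, 0) is fit
by least squares over an exhaustive changepoint grid with prefix-sum updates;
BIC comparison against the constant and all-zero nested models licenses
degenerate records. Ties break toward the earliest `t12`. The reported
phase-1 velocity is the arithmetic mean of the velocity over phase 1.
The transition-density check compares the untagged plateau level just before
`t12` with the median end-tag plateau level; the per-pixel plateau levels are
used rather than the integral densities `I/L`, which lose several percent to
PSF spill at segment boundaries.

## What the generator emulates, and what it does not

The simulator reproduces the features the analysis depends on: the
three-phase velocity profile with overlap-length-set phase-1 velocity,
length-scaled end-tags acting as roadblocks, density compensation in the
shrinking overlap, intensity plateaus ordered single < untagged < end-tag,
3 frames/s sampling, PSF blur and shot noise. It does **not** model
single-molecule binding/unbinding kinetics (no rates are available), force
generation or friction, filament dynamics, bundles of more than two
microtubules, camera read noise, drift, or - importantly - event-to-event
*biological* variability in motor speed. Consequently simulated
velocity-overlap correlations (r ~ 0.9) are much tighter than experimental
ones, and passing round-trip tests demonstrates correctness of the
measurement chain, not robustness to every property of real data.

Two further limitations. (i) When tags nucleate during the record and the
overlap is consumed before they saturate, the tags merge optically while
still growing; tag lengths reported from the last resolved frame then lag
the at-stall truth, and the measured `L_FO/(LET1+LET2)` overshoots 1 by a few
percent - which is why the roadblock analyses use the saturated (pre-formed)
condition. (ii) A final-overlap-vs-length slope much above ~0.45 cannot be
represented: with `L_FO = f (ML1 + ML2)` and `L_FO <= min(ML1, ML2)`, a
fraction of 0.8 per filament is geometrically impossible for comparable
filament lengths, so slope checks use f = 0.3-0.4.

## Numerical choices and identifiability

- Changepoint grids are exhaustive up to 400 candidate frames, strided above.
- `fit_mm` is unweighted nonlinear least squares with `v0` and `K_L` bounded
  by 10x the data scale; initialization `v0 = max(v)`, `K_L = median(L)`.
  Hitting a bound is an error, not a result.
- `K_L` is weakly identified by saturation-arm data: for 60 events with
  10 nm/s velocity noise over 0.5-5 um overlaps at `K_L = 1.5 um`, the
  Cramer-Rao bound already gives sd(K_L)/K_L ~ 0.22, so per-replicate errors
  of ~15% are the information floor, not an estimator deficiency. Recovery
  benchmarks therefore check that the *median recovered* parameter is
  centred on the truth.
- Gaussian histogram fits are bounded (`mu` within the data range, `sigma`
  below twice the span) to stay identifiable on coarse histograms; a
  maximum-likelihood fit on raw values would be more efficient but the
  histogram fit mirrors the standard figure-legend procedure.
- Degenerate inputs reject loudly: zero initial overlap, `dt >= duration`,
  non-odd smoothing windows, traces under 20 frames, zero-variance inputs to
  correlation/regression, histograms of identical values.

## Problem sizes

Validation ensembles use 40-60 events per condition and 50 events for the
round-trip and roadblock benchmarks, with records of 200-450 s at 3 frames/s
and fields of ~15-25 um at 100 nm/px; these sizes give population medians
that are stable at the tolerances quoted while keeping a full run in the
minutes range on one core. Larger ensembles only tighten the same estimates.
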