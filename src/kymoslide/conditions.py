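"""Named simulation conditions.

Each factory returns a :class:`~kymoslide.kymosynth.ConditionSpec` whose
parameters were calibrated once, analytically, against the published
condition-level numbers for the PRC1-Kif4A sliding assay:

* ``low_crosslinker`` (0.2 nM PRC1 + 6 nM Kif4A-GFP like): v0 = 58 nm/s,
  S = 0.095, a = 0.05 chosen so that (i) the mean phase-1 velocity over
  initial overlaps of 0.8-5 um is ~46 nm/s and (ii) a saturating
  velocity-overlap fit over that range returns a half-max overlap
  K_L ~ 1.7 um, the value implied by sliding efficiencies of ~0.3 at 1%
  occupancy down to ~0.03 at 10%. The untagged GFP density is 3.5 +/- 1.7
  A.U./nm across events.
* ``high_crosslinker`` (1 nM PRC1 + 6 nM Kif4A-GFP like): more crosslinker
  recruits more motor (density 6.5 +/- 1.9 A.U./nm, occupancy a = 0.10) but
  crowds the lattice, so the per-complex sliding efficiency drops to
  S = 0.0059, giving a ~4-fold slower mean velocity of ~11 nm/s.
* ``roadblock_saturated``: end-tags pre-formed at their length-scaled plateau
  (fraction 0.4 of each filament), the regime in which the final overlap
  equals the summed end-tag lengths.
* ``roundtrip``: a generic recovery benchmark with pre-formed 0.3-fraction
  end-tags and a longer untagged runway, so every event shows all three
  kinetic phases.
"""

from __future__ import annotations

from dataclasses import replace

from .kymosynth import ConditionSpec

#: Calibrated fluorescence intensity of one GFP-labelled motor (A.U.),
#: as measured on immobilized single molecules; with the low-crosslinker
#: untagged density of 3.5 A.U./nm this corresponds to ~10 molecules per
#: micrometre of overlap.
SINGLE_MOLECULE_INTENSITY = 350.0

_COMMON = dict(
    ml1_range=(4000.0, 10000.0),
    ml2_range=(4000.0, 10000.0),
    v0=58.0,
    delta=8.0,
    duration=300.0,
)


def low_crosslinker(snr: float | None = None, **overrides) -> ConditionSpec:
    """0.2 nM PRC1 + 6 nM Kif4A-GFP-like condition (fast sliding)."""
    spec = ConditionSpec(
        name="low_crosslinker",
        overlap_range=(800.0, 5000.0),
        sliding_efficiency=0.095,
        occupancy=0.05,
        endtag_fraction=0.3,
        rho_untagged_mean=3.5,
        rho_untagged_sd=1.7,
        snr=snr,
        **_COMMON,
    )
    return replace(spec, **overrides) if overrides else spec


def high_crosslinker(snr: float | None = None, **overrides) -> ConditionSpec:
    """1 nM PRC1 + 6 nM Kif4A-GFP-like condition (slow, dense overlaps)."""
    spec = ConditionSpec(
        name="high_crosslinker",
        overlap_range=(800.0, 5000.0),
        sliding_efficiency=0.0059,
        occupancy=0.10,
        endtag_fraction=0.4,
        rho_untagged_mean=6.5,
        rho_untagged_sd=1.9,
        snr=snr,
        **_COMMON,
    )
    return replace(spec, **overrides) if overrides else spec


def roadblock_saturated(snr: float | None = 5.0, **overrides) -> ConditionSpec:
    """Saturated, length-scaled end-tags (fraction 0.4) for roadblock tests."""
    spec = ConditionSpec(
        name="roadblock_saturated",
        overlap_range=(3500.0, 9000.0),
        sliding_efficiency=0.095,
        occupancy=0.05,
        endtag_fraction=0.4,
        endtags_preformed=True,
        snr=snr,
        **_COMMON,
    )
    return replace(spec, **overrides) if overrides else spec


def roundtrip(snr: float | None = 5.0, **overrides) -> ConditionSpec:
    """Recovery benchmark: pre-formed 0.3-fraction end-tags, long runway."""
    spec = ConditionSpec(
        name="roundtrip",
        overlap_range=(3000.0, 9500.0),
        sliding_efficiency=0.095,
        occupancy=0.05,
        endtag_fraction=0.3,
        endtags_preformed=True,
        snr=snr,
        **_COMMON,
    )
    return replace(spec, **overrides) if overrides else spec
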