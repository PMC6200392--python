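"""Quantification: edge detection, end-tag segmentation, intensity accounting
and event-level round trips against rendered ground truth."""



import numpy as np
import pytest

from kymoslide import conditions
from kymoslide.kymograph import GFP_CHANNEL, MT_CHANNEL, Kymograph
from kymoslide.kymosynth import (
    OpticsParams,
    render_kymograph,
    simulate_ensemble,
    simulate_pair,
)
from kymoslide.kymoquant import (
    detect_edges,
    measure_frame,
    segment_end_tags,
    track_event,
)


def _uniform_kymo(value=100.0, frames=5, pixels=120):
    px = np.full((2, frames, pixels), float(value))
    return Kymograph(pixels=px, pixel_size=100.0, frame_interval=1 / 3)


class TestDetectEdges:
    def test_outer_edges_of_noiseless_structures(self, noiseless_event,
                                                 saturated_params):
        traj, kymo = noiseless_event
        p = saturated_params
        edges = detect_edges(kymo, MT_CHANNEL, frame=0)
        # the crosslinked pair forms one structure spanning [0, s0 + ML2]
        assert len(edges) == 2
        assert edges[0] == pytest.approx(0.0, abs=kymo.pixel_size / 2)
        assert edges[1] == pytest.approx(p.s0 + p.ml2, abs=kymo.pixel_size / 2)

    def test_uniform_image_has_no_structure(self):
        kymo = _uniform_kymo()
        for ch in (MT_CHANNEL, GFP_CHANNEL):
            assert detect_edges(kymo, ch, frame=2).size == 0

    def test_frame_and_channel_validation(self):
        kymo = _uniform_kymo()
        with pytest.raises(IndexError):
            detect_edges(kymo, MT_CHANNEL, frame=99)
        with pytest.raises(ValueError):
            detect_edges(kymo, 5, frame=0)

    def test_edge_rmse_within_one_pixel_down_to_snr3(self):
        cond = conditions.roadblock_saturated(snr=3.0)
        events = simulate_ensemble(cond, 3, seed=21)
        errs = []
        for ev in events:
            et = track_event(ev.kymo)
            e = et.edges["moving"]
            errs.append(e.x - ev.traj.s[e.frames])
        rmse = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
        assert rmse <= events[0].kymo.pixel_size


class TestSegmentEndTags:
    def _profile(self, untagged=5.0, endtag=12.0, tag_px=10, total_px=60):
        # overlap occupies [10, 50) px; tags at both overlap ends
        prof = np.zeros(total_px)
        prof[10:50] = untagged
        prof[10:10 + tag_px] = endtag
        prof[50 - tag_px:50] = endtag
        return prof

    def test_constructed_plateaus_give_1um_tags(self):
        prof = self._profile()
        seg = segment_end_tags(prof, (1000.0, 5000.0), pixel_size=100.0,
                               noise=0.5)
        assert seg.resolved
        assert seg.let1 == pytest.approx(1000.0, abs=100.0)
        assert seg.let2 == pytest.approx(1000.0, abs=100.0)

    def test_flat_profile_has_no_end_tags(self):
        prof = np.full(60, 5.0)
        prof[:10] = 0
        prof[50:] = 0
        seg = segment_end_tags(prof, (1000.0, 5000.0), pixel_size=100.0,
                               noise=0.5)
        assert not seg.resolved

    def test_merged_end_tags_flagged_unresolved(self):
        # tags grown into each other: the overlap is uniformly bright
        prof = self._profile(tag_px=20)
        seg = segment_end_tags(prof, (1000.0, 5000.0), pixel_size=100.0,
                               noise=0.5)
        assert not seg.resolved


@pytest.fixture(scope="module")
def long_overlap_kymo():
    # gentle PSF and a long untagged overlap: the rendering oracle for
    # the intensity bookkeeping
    from kymoslide.kymosynth import SimulationParams
    params = SimulationParams(ml1=9000.0, ml2=8000.0, s0=4000.0, duration=30.0)
    optics = OpticsParams(psf_sigma=100.0)
    traj = simulate_pair(params)
    return params, optics, traj, render_kymograph(traj, optics, noise=False)


class TestMeasureFrame:

    def test_untagged_intensity_matches_flux_times_length(self, long_overlap_kymo):
        params, optics, traj, kymo = long_overlap_kymo
        m = measure_frame(kymo, 0)
        assert m.ok
        expected = optics.rho_untagged * traj.untagged[0]
        assert m.I_untagged == pytest.approx(expected, rel=0.02)

    def test_intensity_partition_identity(self, noiseless_event):
        _, kymo = noiseless_event
        m = measure_frame(kymo, 10)
        assert m.endtags_resolved
        assert m.I_overlap == pytest.approx(
            m.I_untagged + m.iet1 + m.iet2, rel=0.01)

    def test_untagged_density_recovers_flux(self, long_overlap_kymo):
        params, optics, traj, kymo = long_overlap_kymo
        m = measure_frame(kymo, 0)
        assert m.rho_untagged == pytest.approx(3.5, abs=0.1)

    def test_uniform_frame_flagged(self):
        kymo = _uniform_kymo()
        m = measure_frame(kymo, 0)
        assert not m.ok
        assert m.reason == "no_structure"


class TestTrackEvent:
    def test_noiseless_roundtrip_within_one_pixel(self, noiseless_event,
                                                  saturated_params):
        traj, kymo = noiseless_event
        p = saturated_params
        et = track_event(kymo)
        px = kymo.pixel_size
        assert et.L0 == pytest.approx(traj.overlap[0], abs=px)
        assert et.L_FO == pytest.approx(traj.final_overlap, abs=px)
        assert et.ml1 == pytest.approx(p.ml1, abs=px)
        assert et.ml2 == pytest.approx(p.ml2, abs=px)
        assert et.let1 == pytest.approx(traj.let1[-1], abs=px)
        assert et.let2 == pytest.approx(traj.let2[-1], abs=px)
        assert abs(et.t_stall - traj.t_stall) < 15.0

    def test_event_without_stall_is_flagged(self):
        from kymoslide.kymosynth import SimulationParams
        p = SimulationParams(ml1=9000.0, ml2=8000.0, s0=2000.0, duration=25.0,
                             record_after_stall=0.0)
        traj = simulate_pair(p)
        assert not traj.stalled
        kymo = render_kymograph(traj, OpticsParams(), noise=False)
        et = track_event(kymo)
        assert np.isnan(et.L_FO)
        assert et.flags.get("no_stall")

    def test_measurements_invariant_to_gfp_intensity_scale(self, noiseless_event):
        _, kymo = noiseless_event
        base = measure_frame(kymo, 5)
        scaled_pixels = kymo.pixels.copy()
        scaled_pixels[GFP_CHANNEL] *= 7.0
        scaled = Kymograph(pixels=scaled_pixels, pixel_size=kymo.pixel_size,
                           frame_interval=kymo.frame_interval,
                           origin=kymo.origin)
        m = measure_frame(scaled, 5)
        assert m.let1 == pytest.approx(base.let1, abs=10.0)
        assert m.let2 == pytest.approx(base.let2, abs=10.0)
        assert m.L_untagged == pytest.approx(base.L_untagged, abs=10.0)
        # intensities scale linearly (background is re-estimated per line)
        assert m.I_untagged == pytest.approx(7.0 * base.I_untagged, rel=0.02)
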