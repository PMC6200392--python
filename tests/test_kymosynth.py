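"""Simulator: trajectory mechanics, invariants and rendering statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymoslide import conditions
from kymoslide.ensemble_stats import linear_fit
from kymoslide.kymosynth import (
    ConditionSpec,
    OpticsParams,
    SimulationParams,
    render_kymograph,
    simulate_ensemble,
    simulate_pair,
    truth_table,
)


class TestTrajectory:
    def test_final_overlap_equals_endtag_sum_exactly(self, basic_params):
        traj = simulate_pair(basic_params)
        assert traj.stalled
        k = np.flatnonzero(traj.phase == 3)[0]
        assert traj.final_overlap == pytest.approx(
            traj.let1[k] + traj.let2[k], abs=1e-9)
        assert traj.overlap[-1] == pytest.approx(traj.final_overlap, abs=1e-6)

    def test_saturated_endtags_stall_geometry(self, saturated_params):
        # LET1 = 2400, LET2 = 2100 at fraction 0.3 -> L_FO = 4500 nm
        traj = simulate_pair(saturated_params)
        assert traj.final_overlap == pytest.approx(4500.0, abs=1e-9)

    def test_zero_efficiency_means_no_sliding(self, basic_params):
        p = dataclasses.replace(basic_params, sliding_efficiency=0.0)
        traj = simulate_pair(p)
        assert np.all(traj.v == 0.0)
        assert np.all(traj.s == p.s0)

    def test_phase1_velocity_constant_while_overlap_shrinks(self, basic_params):
        traj = simulate_pair(basic_params)
        ph1 = traj.phase == 1
        assert ph1.sum() > 10
        assert np.ptp(traj.v[ph1]) < 1e-9
        # the overlap is strictly shrinking during that constant phase
        assert traj.overlap[ph1][-1] < traj.overlap[ph1][0]

    def test_phases_ordered_and_velocity_non_increasing(self, basic_params):
        traj = simulate_pair(basic_params)
        assert np.all(np.diff(traj.phase) >= 0)
        assert np.all(np.diff(traj.v) <= 1e-9)
        assert np.all(traj.v[traj.phase == 3] == 0.0)

    def test_phase1_velocity_depends_only_on_untagged_overlap(self):
        a = SimulationParams(ml1=9000, ml2=5000, s0=5000, duration=100)
        b = SimulationParams(ml1=12000, ml2=8000, s0=8000, duration=100)
        assert a.initial_untagged == b.initial_untagged == 4000.0
        assert a.base_velocity == pytest.approx(b.base_velocity, rel=1e-12)

    @given(
        s=st.floats(0.02, 0.5),
        a=st.floats(0.01, 0.2),
        bump=st.floats(1e-4, 0.2),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_phase1_velocity_monotone_in_efficiency_and_occupancy(self, s, a, bump):
        def v1(s_, a_):
            return SimulationParams(
                ml1=8000, ml2=6000, s0=4000, sliding_efficiency=s_,
                occupancy=a_, duration=50,
            ).base_velocity

        base = v1(s, a)
        assert v1(min(s + bump, 1.0), a) >= base - 1e-12
        assert v1(s, min(a + bump, 1.0)) >= base - 1e-12

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationParams(ml1=4000, ml2=3000, s0=9000)
        with pytest.raises(ValueError, match="dt"):
            SimulationParams(ml1=4000, ml2=3000, s0=2000, duration=1.0, dt=2.0)


class TestRendering:
    def test_noiseless_intensity_integral(self, saturated_params):
        optics = OpticsParams(psf_sigma=0.0, background=0.0)
        traj = simulate_pair(saturated_params)
        kymo = render_kymograph(traj, optics, noise=False)
        # total GFP counts at frame 0 = sum of flux * segment length
        p = saturated_params
        let1, let2 = p.initial_endtags
        lu = p.initial_untagged
        singles = p.ml1 + p.ml2 - 2 * p.initial_overlap
        expected = (optics.rho_endtag * (let1 + let2)
                    + optics.rho_untagged * lu
                    + optics.rho_single * singles)
        assert kymo.gfp[0].sum() == pytest.approx(expected, rel=0.01)

    def test_zero_flux_zero_background_gives_blank_image(self, saturated_params):
        optics = OpticsParams(rho_single=0, rho_untagged=0, rho_endtag=0,
                              mt_flux=0, background=0)
        traj = simulate_pair(saturated_params)
        kymo = render_kymograph(traj, optics, noise=True)
        assert np.all(kymo.pixels == 0)

    def test_poisson_mean_matches_noiseless_profile(self):
        p = SimulationParams(ml1=3000, ml2=2500, s0=1000, duration=3.0)
        traj = simulate_pair(p)
        clean = render_kymograph(traj, OpticsParams(), noise=False)
        acc = np.zeros_like(clean.pixels)
        n = 150
        for seed in range(n):
            rng = np.random.default_rng(seed)
            acc += render_kymograph(traj, OpticsParams(), rng=rng).pixels
        mean = acc / n
        # Poisson: sd of the mean = sqrt(lam/n); allow 5 sigma per pixel
        tol = 5 * np.sqrt(clean.pixels / n)
        assert np.all(np.abs(mean - clean.pixels) < tol + 1e-9)

    def test_rejects_coarse_pixels(self, saturated_params):
        traj = simulate_pair(saturated_params)
        with pytest.raises(ValueError, match="pixel size"):
            render_kymograph(traj, OpticsParams(pixel_size=20000.0))

    def test_snr_scaling_hits_target(self):
        optics = OpticsParams().scaled_to_snr(5.0)
        assert optics.untagged_snr() == pytest.approx(5.0, rel=1e-9)
        mt_plateau = optics.mt_flux * optics.pixel_size
        assert mt_plateau / np.sqrt(mt_plateau + optics.background) == \
            pytest.approx(5.0, rel=1e-9)


class TestEnsembles:
    def test_deterministic_under_seed(self):
        cond = ConditionSpec(name="det", duration=40.0)
        a = simulate_ensemble(cond, 3, seed=7)
        b = simulate_ensemble(cond, 3, seed=7)
        for ea, eb in zip(a, b):
            assert ea.params == eb.params
            np.testing.assert_array_equal(ea.kymo.pixels, eb.kymo.pixels)

    def test_final_overlap_scales_with_microtubule_length(self):
        cond = conditions.roadblock_saturated(snr=None)
        events = simulate_ensemble(cond, 60, seed=11, render=False)
        tt = truth_table(events)
        slope, intercept, r = linear_fit(
            tt["ml1_nm"] + tt["ml2_nm"], tt["final_overlap_nm"])
        assert slope == pytest.approx(cond.endtag_fraction, abs=0.05)
        assert r > 0.95

    def test_longer_initial_overlaps_slide_faster(self):
        cond = conditions.low_crosslinker()
        events = simulate_ensemble(cond, 40, seed=5, render=False)
        tt = truth_table(events)
        order = tt.sort_values("initial_overlap_nm")["v_phase1_nm_s"]
        lo = order.iloc[:10].mean()
        hi = order.iloc[-10:].mean()
        assert hi > lo

    def test_degenerate_distributions_rejected(self):
        cond = ConditionSpec(ml1_range=(1000.0, 1001.0),
                             ml2_range=(1000.0, 1001.0),
                             overlap_range=(5000.0, 6000.0))
        with pytest.raises(RuntimeError, match="valid"):
            simulate_ensemble(cond, 2, seed=0, render=False)
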