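import numpy as np
import pytest

from otokin import oculomotor as oc
from otokin.io_formats import MotionTrace
from otokin.stats import circular_summary, watson_williams
from otokin.synthetic_data import EyeSimConfig, eye_preset, simulate_eyes


def _sine_trace(freq=0.5, amp=10.0, n_cycles=15, fs=200.0, kind="visual", eye=None):
    n = int(round(n_cycles / freq * fs)) + 1
    t = np.arange(n) / fs
    stim = amp * np.sin(2 * np.pi * freq * t)
    eyes = [eye if eye is not None else stim.copy()]
    return MotionTrace(fs, stim, eyes, stimulus_kind=kind, stimulus_freq=freq,
                       stimulus_amplitude=amp)


class TestPreprocess:
    def test_passband_amplitude_preserved(self):
        # 0.5 Hz is far below the 4 Hz cutoff
        pre = oc.preprocess(_sine_trace())
        mid = slice(400, -400)
        assert np.ptp(pre.stimulus[mid]) == pytest.approx(20.0, rel=0.01)
        assert pre.sample_rate == 200.0

    def test_out_of_band_noise_attenuated_20db(self):
        trace = _sine_trace()
        t = trace.time
        contaminated = trace.eyes[0] + 2.0 * np.sin(2 * np.pi * 10.0 * t)
        trace.eyes[0] = contaminated
        pre = oc.preprocess(trace)
        # amplitude of the residual 10 Hz component via quadrature projection
        tq = pre.time
        comp = 2 * np.abs(np.mean(pre.eyes[0] * np.exp(-2j * np.pi * 10.0 * tq)))
        assert comp < 2.0 / 10.0  # > 20 dB down

    def test_conjugate_average_of_identical_eyes(self):
        trace = _sine_trace()
        trace.eyes = [trace.eyes[0], trace.eyes[0].copy()]
        pre = oc.preprocess(trace)
        ref = oc.preprocess(_sine_trace())
        np.testing.assert_allclose(pre.eyes[0], ref.eyes[0], atol=1e-9)

    def test_too_short_trace_rejected(self):
        with pytest.raises(oc.InputError):
            oc.preprocess(_sine_trace(n_cycles=1))


class TestSegmentCycles:
    def test_fifteen_cycles_give_fourteen_segments(self):
        pre = oc.preprocess(_sine_trace(n_cycles=15))
        segs = oc.segment_cycles(pre)
        assert len(segs) == 14
        assert not any(s.excluded for s in segs)

    def test_twenty_cycle_protocol_not_truncated(self):
        pre = oc.preprocess(_sine_trace(n_cycles=20))
        assert len(oc.segment_cycles(pre)) == 19

    def test_single_inserted_fast_phase_flags_exactly_that_cycle(self):
        res = simulate_eyes(EyeSimConfig(gain=0.29, phase=-54.3, noise_sd=0.0))
        trace = res.trace
        # inject a 100 ms resetting step inside cycle 6
        t = trace.time
        t0 = 13.1  # within the 7th peak-to-peak segment (cycles start at t=0.5)
        ramp = 6.0 * np.clip((t - t0) / 0.1, 0, 1)
        trace.eyes = [trace.eyes[0] + ramp]
        segs = oc.segment_cycles(oc.preprocess(trace))
        flagged = [i for i, s in enumerate(segs) if s.excluded]
        assert flagged == [6]

    def test_manual_exclusion_respected(self):
        pre = oc.preprocess(_sine_trace())
        segs = oc.segment_cycles(pre, manual_exclude=[0, 3])
        assert [i for i, s in enumerate(segs) if s.excluded] == [0, 3]

    def test_too_few_peaks_rejected(self):
        trace = _sine_trace(n_cycles=15)
        trace.stimulus = np.ones_like(trace.stimulus)
        with pytest.raises(oc.InputError):
            oc.segment_cycles(trace)


class TestAverageCycles:
    def test_identical_cycles_average_equals_single(self):
        pre = oc.preprocess(_sine_trace(n_cycles=10))
        segs = oc.segment_cycles(pre)
        avg = oc.average_cycles(segs)
        single = np.interp(
            avg.phase_grid,
            (segs[0].time - segs[0].time[0]) / (segs[0].time[-1] - segs[0].time[0]),
            segs[0].eye,
        )
        np.testing.assert_allclose(avg.mean_eye, single, atol=1e-6)
        assert avg.n_cycles_used == 9

    def test_noise_shrinks_as_sqrt_n(self):
        # averaging 20 cycles of iid noise should shrink the residual ~sqrt(20)
        rng = np.random.default_rng(0)
        grid = np.arange(200) / 200.0
        clean = np.sin(2 * np.pi * grid)
        segs = []
        t = np.arange(201) / 200.0
        for _ in range(20):
            noisy = np.interp(t / t[-1], grid, clean) + rng.normal(0, 0.5, 201)
            segs.append(oc.CycleSegment(time=t, stimulus=np.interp(t / t[-1], grid, clean),
                                        eye=noisy))
        avg = oc.average_cycles(segs)
        resid_avg = np.std(avg.mean_eye - clean)
        assert resid_avg == pytest.approx(0.5 / np.sqrt(20), rel=0.35)

    def test_alternating_offsets_cancel(self):
        pre = oc.preprocess(_sine_trace(n_cycles=10))
        segs = oc.segment_cycles(pre)
        for k, s in enumerate(segs):
            s.eye = s.eye + (0.5 if k % 2 == 0 else -0.5)
        avg = oc.average_cycles(segs[:8])
        ref = oc.average_cycles(oc.segment_cycles(oc.preprocess(_sine_trace(n_cycles=10)))[:8])
        assert np.mean(avg.mean_eye) - np.mean(ref.mean_eye) == pytest.approx(0.0, abs=1e-9)

    def test_all_excluded_raises_quality_error(self):
        pre = oc.preprocess(_sine_trace(n_cycles=5))
        segs = oc.segment_cycles(pre)
        for s in segs:
            s.excluded = True
        with pytest.raises(oc.QualityError):
            oc.average_cycles(segs)


class TestGainPhase:
    def test_eye_equals_stimulus_unity_gain_zero_phase(self):
        pre = oc.preprocess(_sine_trace(kind="visual"))
        avg = oc.average_cycles(oc.segment_cycles(pre))
        avg.stimulus_kind = "visual"
        gp = oc.gain_phase(avg)
        assert gp.gain == pytest.approx(1.0, abs=0.01)
        assert gp.phase == pytest.approx(0.0, abs=0.5)
        assert gp.condition == "OKR"

    @pytest.mark.parametrize(
        "preset,cond,gain,phase",
        [
            ("xenopus_54", "vor_dark", 0.29, -54.3),
            ("axolotl_54", "vor_dark", 0.05, 47.06),
            ("xenopus_54", "okr", 0.14, 13.4),
        ],
    )
    def test_published_means_recovered_noiselessly(self, preset, cond, gain, phase):
        res = simulate_eyes(eye_preset(preset, cond))
        gp = oc.estimate_gain_phase(res.trace)
        assert gp.gain == pytest.approx(gain, abs=0.01)
        assert gp.phase == pytest.approx(phase, abs=2.0)

    @pytest.mark.parametrize("gain", [0.05, 0.14, 0.25, 0.29, 0.32])
    @pytest.mark.parametrize("phase", [-54.3, 0.0, 47.06])
    def test_recovery_under_noise(self, gain, phase):
        res = simulate_eyes(EyeSimConfig(gain=gain, phase=phase, noise_sd=0.5, seed=3))
        gp = oc.estimate_gain_phase(res.trace)
        assert gp.gain == pytest.approx(gain, abs=0.01)
        assert gp.phase == pytest.approx(phase, abs=3.0)

    def test_gain_invariant_to_eye_offset(self):
        res = simulate_eyes(EyeSimConfig(gain=0.29, phase=-54.3, noise_sd=0.0))
        gp0 = oc.estimate_gain_phase(res.trace)
        res.trace.eyes = [e + 4.2 for e in res.trace.eyes]
        gp1 = oc.estimate_gain_phase(res.trace)
        assert gp1.gain == pytest.approx(gp0.gain, abs=1e-6)

    def test_phase_invariant_to_stimulus_scaling(self):
        res = simulate_eyes(EyeSimConfig(gain=0.29, phase=-54.3, noise_sd=0.0))
        gp0 = oc.estimate_gain_phase(res.trace)
        res.trace.stimulus = res.trace.stimulus * 2.5
        gp1 = oc.estimate_gain_phase(res.trace)
        assert gp1.phase == pytest.approx(gp0.phase, abs=0.1)
        assert gp1.gain == pytest.approx(gp0.gain / 2.5, rel=0.01)

    def test_excluding_clean_cycles_barely_moves_estimate(self):
        res = simulate_eyes(EyeSimConfig(gain=0.29, phase=-54.3, noise_sd=0.2, seed=9))
        gp0 = oc.estimate_gain_phase(res.trace)
        gp1 = oc.estimate_gain_phase(res.trace, manual_exclude=[2, 5, 11])
        assert gp1.gain == pytest.approx(gp0.gain, abs=0.01)
        assert gp1.phase == pytest.approx(gp0.phase, abs=2.0)

    def test_flat_stimulus_rejected(self):
        avg = oc.CycleAverage(
            phase_grid=np.arange(200) / 200.0,
            mean_eye=np.sin(np.arange(200) / 200.0 * 2 * np.pi),
            mean_stimulus=np.zeros(200),
            n_cycles_used=5,
            excluded_cycles=[],
            period=2.0,
            stimulus_kind="visual",
        )
        with pytest.raises(oc.InputError):
            oc.gain_phase(avg)


class TestCircularStats:
    def test_equal_phases_full_strength(self):
        s = circular_summary([30.0] * 8)
        assert s.mean_direction == pytest.approx(30.0)
        assert s.r == pytest.approx(1.0)

    def test_balanced_spread_zero_strength(self):
        s = circular_summary([0.0, 90.0, 180.0, 270.0])
        assert s.r == pytest.approx(0.0, abs=1e-12)

    def test_two_angle_closed_form(self):
        # resultant of {10, 50} degrees: mean 30, r = cos(20 deg)
        s = circular_summary([10.0, 50.0])
        assert s.mean_direction == pytest.approx(30.0)
        assert s.r == pytest.approx(np.cos(np.deg2rad(20.0)))

    def test_wraparound_mean(self):
        s = circular_summary([170.0, -170.0])
        assert s.mean_direction == pytest.approx(180.0)


class TestWatsonWilliams:
    def test_identical_groups_f_near_zero(self):
        g = [10.0, 12.0, 8.0, 11.0, 9.0]
        F, p = watson_williams(g, list(g))
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_ninety_degree_offset_highly_significant(self):
        rng = np.random.default_rng(1)
        g1 = np.rad2deg(rng.vonmises(0.0, 50.0, 10))
        g2 = np.rad2deg(rng.vonmises(np.pi / 2, 50.0, 10))
        _, p = watson_williams(g1, g2)
        assert p < 0.001

    def test_type_one_error_calibrated_under_null(self):
        # 1000 simulated null comparisons of von Mises groups, alpha = 0.05
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            g1 = np.rad2deg(rng.vonmises(0.5, 8.0, 12))
            g2 = np.rad2deg(rng.vonmises(0.5, 8.0, 12))
            _, p = watson_williams(g1, g2)
            rejections += p < 0.05
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_small_group_rejected(self):
        with pytest.raises(Exception):
            watson_williams([1.0], [2.0, 3.0])
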