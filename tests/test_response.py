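"""Per-response stage: binning, amplitude, background, assembly, controls."""

import numpy as np
import pytest

from polspike import (
    NeuronModel,
    ProtocolSpec,
    analyze_response,
    background_activity,
    bin_response,
    no_stimulus_control,
    normalized_extremes,
    response_amplitude,
    simulate_recording,
)
from polspike.response import ProtocolError, amplitude_from_counts
from polspike.types import PolarizerRotation, StimulusEpoch

from conftest import make_epoch, make_recording


class TestBinResponse:
    def test_single_direction_epoch_rejected(self):
        rot = PolarizerRotation(10.5, "CW", 0.0, 40.0)
        epoch = StimulusEpoch(t_on=10.0, t_off=20.0, dop=0.99, rotations=[rot])
        rec = make_recording([11.0], [epoch], duration=60.0)
        with pytest.raises(ProtocolError):
            bin_response(rec, epoch)

    def test_no_spikes_all_zero(self):
        epoch = make_epoch(t_on=10.0)
        rec = make_recording([], [epoch], duration=60.0)
        binned = bin_response(rec, epoch)
        assert binned.counts.sum() == 0
        assert np.all(binned.rates == 0)

    def test_spike_at_known_angle_lands_in_its_bin(self):
        # CW from 0 deg at 40 deg/s: polarizer reaches 37 deg at t_start+0.925
        epoch = make_epoch(t_on=10.0, start_angle=0.0)
        t_spike = epoch.rotations[0].t_start + 37.0 / 40.0
        rec = make_recording([t_spike], [epoch], duration=60.0)
        binned = bin_response(rec, epoch)
        assert binned.counts[3] == 1  # bin [30, 40)
        assert binned.counts.sum() == 1

    def test_constant_speed_equal_exposures(self):
        epoch = make_epoch(t_on=10.0, speed=40.0)
        rec = make_recording([], [epoch], duration=60.0)
        binned = bin_response(rec, epoch)
        # two 360-deg sweeps at 40 deg/s: 2 * (2 * 10 deg / 40 deg/s) per bin
        assert np.allclose(binned.exposure, 1.0)

    def test_angles_beyond_180_fold_onto_axial_bins(self):
        epoch = make_epoch(t_on=10.0, start_angle=0.0)
        t_spike = epoch.rotations[0].t_start + 217.0 / 40.0  # polarizer at 217 deg
        rec = make_recording([t_spike], [epoch], duration=60.0)
        binned = bin_response(rec, epoch)
        assert binned.counts[3] == 1  # 217 mod 180 = 37 -> bin [30, 40)


class TestResponseAmplitude:
    def test_equal_counts_zero_amplitude(self):
        assert amplitude_from_counts([5] * 18) == 0.0

    def test_single_loaded_bin_hand_computation(self):
        counts = np.zeros(18)
        counts[0] = 10
        # n_bar = 10/18; A = |10 - 10/18| + 17 * 10/18 = 18.888...
        assert amplitude_from_counts(counts) == pytest.approx(18.8888888889)

    def test_against_brute_force_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            counts = rng.poisson(10, 18).astype(float)
            nbar = counts.sum() / 18
            oracle = sum(abs(c - nbar) for c in counts)
            assert amplitude_from_counts(counts) == pytest.approx(oracle, abs=1e-12)

    def test_cyclic_shift_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(8, 18).astype(float)
        for k in range(18):
            assert amplitude_from_counts(np.roll(counts, k)) == pytest.approx(
                amplitude_from_counts(counts))

    def test_scales_linearly(self):
        counts = np.arange(18.0)
        assert amplitude_from_counts(3.0 * counts) == pytest.approx(
            3.0 * amplitude_from_counts(counts))

    def test_averaged_across_rotations(self):
        epoch = make_epoch(t_on=10.0)
        # one spike in the CW sweep only: per-rotation A values differ
        t_spike = epoch.rotations[0].t_start + 0.1
        rec = make_recording([t_spike], [epoch], duration=60.0)
        binned = bin_response(rec, epoch)
        a_cw = amplitude_from_counts(binned.per_rotation_counts[0])
        a_ccw = amplitude_from_counts(binned.per_rotation_counts[1])
        assert response_amplitude(binned) == pytest.approx((a_cw + a_ccw) / 2)


class TestBackground:
    def test_constant_rate(self):
        epoch = make_epoch(t_on=10.0)
        spikes = np.arange(0.05, 10.0, 0.1)  # 10 sp/s
        rec = make_recording(spikes, [epoch], duration=60.0)
        ba = background_activity(rec, epoch)
        assert (ba.median, ba.p2_5, ba.p97_5) == (10.0, 10.0, 10.0)
        assert ba.n_bins == 5 and not ba.truncated

    def test_known_bin_counts_median(self):
        epoch = make_epoch(t_on=10.0)
        spikes = []
        for i, n in enumerate([2, 4, 6, 8, 10]):  # bins (5,6], ..., (9,10]
            spikes.extend(5.0 + i + (np.arange(n) + 0.5) / (n + 1))
        rec = make_recording(sorted(spikes), [epoch], duration=60.0)
        ba = background_activity(rec, epoch)
        assert ba.median == 6.0

    def test_silent_background_all_zero(self):
        epoch = make_epoch(t_on=10.0)
        rec = make_recording([20.0], [epoch], duration=60.0)
        ba = background_activity(rec, epoch)
        assert ba.median == 0.0 and ba.p97_5 == 0.0

    def test_truncated_window_flagged(self):
        epoch = make_epoch(t_on=3.0)
        rec = make_recording([0.5, 1.5], [epoch], duration=60.0)
        ba = background_activity(rec, epoch)
        assert ba.truncated and ba.n_bins == 3

    def test_missing_background_flagged(self):
        epoch = make_epoch(t_on=0.5)
        rec = make_recording([], [epoch], duration=60.0)
        ba = background_activity(rec, epoch)
        assert ba.missing


class TestAnalyzeResponse:
    def test_strong_modulation_recovers_truth(self):
        model = NeuronModel(baseline=20.0, phi_max_true=70.0, amp_law="linear",
                            amp_params=(15.0,), rate_ceiling=60.0)
        proto = ProtocolSpec(dop_ladder=(0.99,))
        hits = 0
        for seed in range(40):
            rec = simulate_recording(model, proto, seed)
            tr = analyze_response(rec, rec.epochs[0])
            d = abs(tr.phi_max - 70.0) % 180.0
            hits += min(d, 180.0 - d) <= 10.0 and tr.significant
        assert hits >= 36

    def test_too_few_spikes_flagged_untestable(self):
        epoch = make_epoch(t_on=10.0)
        t_spike = epoch.rotations[0].t_start + 1.0
        rec = make_recording([t_spike], [epoch], duration=60.0)
        tr = analyze_response(rec, epoch)
        assert not tr.significant
        assert np.isnan(tr.p)
        assert "untestable" in tr.flags

    def test_phi_min_orthogonal_to_phi_max(self):
        model = NeuronModel(baseline=20.0, phi_max_true=10.0, amp_law="linear",
                            amp_params=(15.0,), rate_ceiling=60.0)
        rec = simulate_recording(model, ProtocolSpec(dop_ladder=(0.99,)), 3)
        tr = analyze_response(rec, rec.epochs[0])
        assert (tr.phi_min - tr.phi_max) % 180.0 == pytest.approx(90.0)

    def test_mean_rate_is_spikes_over_rotation_time(self):
        epoch = make_epoch(t_on=10.0)
        spikes = np.linspace(epoch.rotations[0].t_start + 0.01,
                             epoch.rotations[1].t_end - 0.01, 36)
        rec = make_recording(spikes, [epoch], duration=60.0)
        tr = analyze_response(rec, epoch, fit_curve=False)
        assert tr.mean_rate == pytest.approx(36 / 18.0)

    def test_power_monotone_in_modulation_depth(self):
        proto = ProtocolSpec(dop_ladder=(0.99,))
        rates = []
        for m0 in (0.0, 5.0, 15.0):
            model = NeuronModel(baseline=20.0, phi_max_true=45.0,
                                amp_law="linear", amp_params=(m0,),
                                rate_ceiling=60.0)
            sig = 0
            for seed in range(60):
                rec = simulate_recording(model, proto, seed)
                sig += analyze_response(rec, rec.epochs[0],
                                        fit_curve=False).significant
            rates.append(sig)
        assert rates[0] < rates[1] < rates[2]


class TestNormalization:
    def _result(self, rate_max, rate_min, ba_median):
        epoch = make_epoch(t_on=10.0)
        spikes = np.arange(0.05, 10.0, 1.0 / max(ba_median, 0.1))[:int(10 * ba_median)]
        rec = make_recording(np.sort(spikes), [epoch], duration=60.0)
        tr = analyze_response(rec, epoch, fit_curve=False)
        tr.rate_phi_max, tr.rate_phi_min = rate_max, rate_min
        return tr

    def test_ratio_arithmetic(self):
        tr = self._result(30.0, 0.0, 20.0)
        tr.background.median = 20.0
        act_max, act_min = normalized_extremes(tr)
        assert act_max == pytest.approx(1.5)
        assert act_min == 0.0

    def test_zero_background_flagged_not_infinite(self):
        tr = self._result(30.0, 5.0, 0.0)
        tr.background.median = 0.0
        act_max, act_min = normalized_extremes(tr)
        assert act_max is None and act_min is None
        assert "undefined_normalization" in tr.flags


class TestNoStimulusControl:
    def test_homogeneous_background_matches_null_resultant(self):
        """E[r] under homogeneous Poisson spiking approaches the analytic
        null sqrt(pi)/(2 sqrt(n)) for the realized spike count."""
        model = NeuronModel(baseline=30.0, amp_law="linear", amp_params=(0.0,),
                            rate_ceiling=40.0)
        proto = ProtocolSpec(dop_ladder=(0.99,))
        ratios = []
        for seed in range(1000):
            rec = simulate_recording(model, proto, seed)
            ctl = no_stimulus_control(rec, rec.epochs[0])
            if ctl is None:
                continue
            ratios.append(ctl.r / (np.sqrt(np.pi) / (2 * np.sqrt(ctl.n))))
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_silent_background_skipped(self):
        epoch = make_epoch(t_on=30.0)
        rec = make_recording([31.0, 32.0], [epoch], duration=60.0)
        assert no_stimulus_control(rec, epoch) is None

    def test_insufficient_window_skipped(self):
        epoch = make_epoch(t_on=10.0)  # needs 5 + 18.5 s free, has 10
        rec = make_recording(np.arange(0.5, 9.5, 0.2), [epoch], duration=60.0)
        assert no_stimulus_control(rec, epoch) is None

    def test_rhythmic_background_exceeds_homogeneous_null(self):
        """Slow intrinsic rhythm inflates the sham directedness."""
        rng = np.random.default_rng(0)
        epoch = make_epoch(t_on=40.0)
        t = np.arange(0, 40, 0.001)
        lam = 30.0 * (1 + 0.9 * np.sin(2 * np.pi * (1.0 / 9.0) * t)) * 0.001
        spikes = t[rng.uniform(size=t.size) < lam]
        rec = make_recording(spikes, [epoch], duration=80.0)
        ctl = no_stimulus_control(rec, epoch)
        assert ctl.r > 2 * np.sqrt(np.pi) / (2 * np.sqrt(ctl.n))
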