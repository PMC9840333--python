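import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurochirp import synth, tms


def flat_trial(n=4000, rate=4000.0, pulses=(0.2,), protocol="baseline"):
    return tms.EMGTrial(
        trace=np.zeros(n), rate=rate, pulse_times_s=pulses, protocol=protocol
    )


class TestPeakToPeak:
    def test_max_minus_min(self):
        trial = flat_trial()
        i = int((0.2 + 0.025) * trial.rate)
        trace = trial.trace.copy()
        trace[i], trace[i + 10] = 1.2, -0.8
        trial = tms.EMGTrial(trace=trace, rate=trial.rate, pulse_times_s=(0.2,))
        assert tms.peak_to_peak(trial).p2p_amplitude == pytest.approx(2.0)

    def test_flat_trace_zero(self):
        assert tms.peak_to_peak(flat_trial()).p2p_amplitude == 0.0

    def test_window_outside_trace_rejected(self):
        trial = flat_trial(n=900)  # 0.225 s at 4 kHz: window end falls outside
        with pytest.raises(ValueError, match="outside"):
            tms.peak_to_peak(trial)

    @given(offset=st.floats(-5.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_offset_invariance(self, offset):
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(protocol="baseline", n_trials=1, seed=8)
        )
        base = tms.peak_to_peak(trials[0]).p2p_amplitude
        shifted = tms.EMGTrial(
            trace=trials[0].trace + offset,
            rate=trials[0].rate,
            pulse_times_s=trials[0].pulse_times_s,
        )
        assert tms.peak_to_peak(shifted).p2p_amplitude == pytest.approx(base)


class TestPairedPulseRatio:
    @staticmethod
    def _trials(p2p, n=5, seed=0):
        return synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="baseline", mep_amplitude_mv=p2p, n_trials=n,
                noise_mv=0.001, seed=seed,
            )
        )

    def test_inhibition(self):
        ratio = tms.paired_pulse_ratio(self._trials(0.5), self._trials(1.0, seed=1))
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_facilitation(self):
        ratio = tms.paired_pulse_ratio(self._trials(2.0), self._trials(1.0, seed=1))
        assert ratio == pytest.approx(2.0, abs=0.15)

    def test_identical_sets_give_one(self):
        trials = self._trials(1.0)
        assert tms.paired_pulse_ratio(trials, trials) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            tms.paired_pulse_ratio([flat_trial()], [flat_trial()])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            tms.paired_pulse_ratio([], [flat_trial()])


class TestLICIRatio:
    def test_programmed_suppression_recovered(self):
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="LICI100", programmed_ratio=0.4, n_trials=15,
                noise_mv=0.005, seed=3,
            )
        )
        ratio, excluded = tms.lici_ratio(trials)
        assert ratio == pytest.approx(0.4, abs=0.05)
        assert excluded == []

    def test_unity_trials(self):
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="LICI220", programmed_ratio=1.0, n_trials=10,
                noise_mv=0.002, seed=4,
            )
        )
        ratio, _ = tms.lici_ratio(trials)
        assert ratio == pytest.approx(1.0, abs=0.05)

    @staticmethod
    def _absent_first_mep_trial(rng, rate=4000.0):
        """Noisy trace whose first-MEP window is quieter than the pre-pulse
        noise floor (no response to the first pulse)."""
        trace = 0.05 * rng.standard_normal(4000)
        w0 = int((0.2 + 0.015) * rate)
        w1 = int((0.2 + 0.060) * rate)
        trace[w0:w1] = 0.0
        return tms.EMGTrial(trace=trace, rate=rate, pulse_times_s=(0.2, 0.3))

    def test_noise_floor_exclusion(self):
        rng = np.random.default_rng(5)
        trials = [self._absent_first_mep_trial(rng) for _ in range(5)]
        with pytest.raises(ValueError, match="excluded"):
            tms.lici_ratio(trials)

    def test_noise_floor_partial_exclusion(self):
        good = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="LICI100", programmed_ratio=0.5, n_trials=6,
                noise_mv=0.005, seed=5,
            )
        )
        bad = self._absent_first_mep_trial(np.random.default_rng(6))
        ratio, excluded = tms.lici_ratio(good + [bad])
        assert excluded == [6]
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_single_pulse_trial_rejected(self):
        with pytest.raises(ValueError, match="2 pulses"):
            tms.lici_ratio([flat_trial()])

    def test_consistency_with_paired_pulse_ratio(self):
        # when every first MEP equals the baseline mean, the two routes agree
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="LICI100", programmed_ratio=0.6, n_trials=12,
                noise_mv=0.0005, seed=6,
            )
        )
        lici, _ = tms.lici_ratio(trials)
        firsts = [
            tms.peak_to_peak(t, pulse_index=0).p2p_amplitude for t in trials
        ]
        seconds = [
            tms.peak_to_peak(t, pulse_index=1).p2p_amplitude for t in trials
        ]
        per_trial = np.mean(np.array(seconds) / np.array(firsts))
        assert lici == pytest.approx(per_trial, abs=1e-12)


class TestCSP:
    def test_programmed_duration_recovered(self):
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(protocol="CSP", programmed_csp_ms=150, noise_mv=0.005, seed=7)
        )
        durations = [tms.csp_duration(t)[0] for t in trials]
        assert np.mean(durations) == pytest.approx(150.0, abs=5.0)

    def test_no_silence_flagged_short(self):
        # continuous contraction with an MEP but no programmed silence:
        # reported duration collapses to roughly the MEP offset
        rng = np.random.default_rng(9)
        rate = 4000.0
        trace = 0.15 * rng.standard_normal(4000)
        t = np.arange(int(0.030 * rate)) / rate
        mep = 1.5 * np.sin(2 * np.pi * 60.0 * t) * np.exp(-((t - 0.008) ** 2) / 1e-4)
        i0 = int((0.4 + 0.018) * rate)
        trace[i0 : i0 + len(mep)] += mep
        trial = tms.EMGTrial(trace=trace, rate=rate, pulse_times_s=(0.4,), protocol="CSP")
        duration, short = tms.csp_duration(trial)
        assert short
        assert duration < 100.0

    def test_no_contraction_rejected(self):
        trial = tms.EMGTrial(
            trace=np.zeros(4000), rate=4000.0, pulse_times_s=(0.4,), protocol="CSP"
        )
        with pytest.raises(ValueError, match="contraction"):
            tms.csp_duration(trial)


class TestIOCurve:
    @staticmethod
    def _trials_by_intensity(seed=0):
        out = {}
        for i, pct in enumerate(range(100, 160, 10)):
            out[pct] = synth.simulate_emg_trials(
                synth.EMGSimParams(
                    protocol=f"IO_{pct}", mep_amplitude_mv=0.2 + 0.4 * i,
                    n_trials=8, noise_mv=0.005, seed=seed + i,
                )
            )
        return out

    def test_monotone_recruitment(self):
        curve = tms.io_curve(self._trials_by_intensity())
        assert (np.diff(curve["mean_p2p"]) > 0).all()
        assert list(curve["intensity_pct_rmt"]) == [100, 110, 120, 130, 140, 150]

    def test_single_intensity(self):
        trials = self._trials_by_intensity()
        curve = tms.io_curve({120: trials[120]})
        assert len(curve) == 1

    def test_mean_matches_hand_computation(self):
        trials = self._trials_by_intensity()[130]
        curve = tms.io_curve({130: trials})
        hand = np.mean([tms.peak_to_peak(t).p2p_amplitude for t in trials])
        assert curve["mean_p2p"].iloc[0] == pytest.approx(hand)

    def test_unknown_intensity_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            tms.io_curve({"mystery": [flat_trial()]})


class TestRatioRecoveryProperty:
    @pytest.mark.parametrize("ratio", [0.3, 0.5, 1.0, 1.5, 2.0])
    def test_lici_programmed_ratio_recovered(self, ratio):
        trials = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="LICI100", programmed_ratio=ratio, n_trials=15,
                noise_mv=0.01, seed=int(ratio * 10),
            )
        )
        got, _ = tms.lici_ratio(trials)
        assert got == pytest.approx(ratio, rel=0.10)

    @pytest.mark.parametrize("ratio", [0.3, 0.5, 1.0, 1.5, 2.0])
    def test_conditioned_programmed_ratio_recovered(self, ratio):
        base = synth.simulate_emg_trials(
            synth.EMGSimParams(protocol="baseline", n_trials=15, noise_mv=0.01, seed=1)
        )
        cond = synth.simulate_emg_trials(
            synth.EMGSimParams(
                protocol="SICI2", programmed_ratio=ratio, n_trials=15,
                noise_mv=0.01, seed=int(ratio * 10) + 50,
            )
        )
        assert tms.paired_pulse_ratio(cond, base) == pytest.approx(ratio, rel=0.10)


class TestSummarizeProtocols:
    def test_summary_table(self):
        blocks = {
            "baseline": synth.simulate_emg_trials(
                synth.EMGSimParams(protocol="baseline", n_trials=10, noise_mv=0.005, seed=1)
            ),
            "SICI2": synth.simulate_emg_trials(
                synth.EMGSimParams(protocol="SICI2", programmed_ratio=0.5, n_trials=10,
                                   noise_mv=0.005, seed=2)
            ),
            "LICI100": synth.simulate_emg_trials(
                synth.EMGSimParams(protocol="LICI100", programmed_ratio=0.4, n_trials=10,
                                   noise_mv=0.005, seed=3)
            ),
            "CSP": synth.simulate_emg_trials(
                synth.EMGSimParams(protocol="CSP", programmed_csp_ms=120, noise_mv=0.005, seed=4)
            ),
        }
        table = tms.summarize_protocols(blocks, subject_id="s1")
        by_proto = table.set_index("protocol")
        assert by_proto.loc["SICI2", "value"] == pytest.approx(0.5, abs=0.05)
        assert by_proto.loc["LICI100", "value"] == pytest.approx(0.4, abs=0.05)
        assert by_proto.loc["CSP", "value"] == pytest.approx(120.0, abs=5.0)

    def test_paired_protocol_without_baseline_rejected(self):
        blocks = {
            "SICI2": synth.simulate_emg_trials(
                synth.EMGSimParams(protocol="SICI2", n_trials=3, seed=2)
            )
        }
        with pytest.raises(ValueError, match="baseline"):
            tms.summarize_protocols(blocks)
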