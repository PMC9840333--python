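"""Synthetic chirp-EEG sessions and TMS-EMG trial generators.

Everything here is a pure function of its parameters and a seed, so the
whole downstream pipeline can be exercised and calibrated without any
recorded data.  The EEG generator produces:

* per-channel 1/f background noise,
* a phase-locked low-frequency burst at stimulus onset,
* an entrained component whose instantaneous frequency tracks the
  stimulus amplitude-modulation sweep during the 2 s of stimulation,
* optional blink-like frontal transients and bad channels.

Trial-to-trial phase variability is modelled with a von Mises
distribution: concentration ``kappa = 0`` gives uniform phases (the
no-locking null with an analytic inter-trial-coherence expectation of
``sqrt(pi / (4 n))``), ``kappa -> inf`` gives perfect locking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Recording, ROI_DEFINITIONS

__all__ = [
    "StimulusWaveform",
    "TrialSchedule",
    "SimParams",
    "EMGSimParams",
    "DEFAULT_CHANNELS",
    "EMG_PROTOCOLS",
    "make_chirp_stimulus",
    "make_trial_schedule",
    "simulate_eeg_session",
    "simulate_emg_trials",
]

# kappa above this is treated as perfect phase locking
_KAPPA_PERFECT = 1e6

#: The 22 ROI electrodes plus 10 fillers (32 channels total).
DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    dict.fromkeys(
        [ch for roi in ROI_DEFINITIONS.values() for ch in roi.electrodes]
        + ["Fp1", "Fp2", "F7", "F8", "T7", "T8", "CP1", "CP2", "P7", "P8"]
    )
)

# crude scalp gain of the evoked components per electrode-name prefix;
# strongest over frontal sites, falling off towards occipital
_REGION_GAIN = {
    "Fp": 0.9, "AF": 0.9, "FC": 0.9, "F": 1.0,
    "C": 0.8, "CP": 0.7, "T": 0.5, "P": 0.7, "PO": 0.5, "O": 0.5,
}


def _channel_gain(name: str) -> float:
    for prefix in sorted(_REGION_GAIN, key=len, reverse=True):
        if name.startswith(prefix):
            return _REGION_GAIN[prefix]
    return 0.5


@dataclass(frozen=True)
class StimulusWaveform:
    """An amplitude-modulated tone with a linear AM frequency sweep."""

    samples: np.ndarray
    rate: float
    carrier_hz: float
    am_f0: float
    am_f1: float
    duration_s: float

    def am_instantaneous_hz(self, t: float | np.ndarray) -> np.ndarray:
        """AM frequency at time ``t`` (linear sweep from am_f0 to am_f1)."""
        return self.am_f0 + (self.am_f1 - self.am_f0) * np.asarray(t) / self.duration_s


@dataclass(frozen=True)
class TrialSchedule:
    """Stimulus onset times with jittered inter-stimulus gaps."""

    onsets: np.ndarray
    n_trials: int
    isi_bounds_ms: tuple[float, float]
    stimulus_duration_s: float
    seed: int

    @property
    def session_duration_s(self) -> float:
        return float(self.onsets[-1] + self.stimulus_duration_s)


@dataclass(frozen=True)
class SimParams:
    """Controls for one synthetic EEG session.

    ``phase_locking_kappa`` applies to both the onset burst and the
    entrained component; 0 means uniform (unlocked) trial phases.
    """

    group_label: str = "control"
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    onset_theta_gain: float = 4.0
    onset_theta_freq: float = 5.0
    entrain_gain: float = 3.0
    phase_locking_kappa: float = 2.0
    noise_exponent: float = 1.0
    noise_scale: float = 20.0
    artifact_rate_per_min: float = 0.0
    bad_channel_labels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_locking_kappa < 0:
            raise ValueError("phase_locking_kappa must be >= 0")
        if min(self.onset_theta_gain, self.entrain_gain, self.noise_scale) < 0:
            raise ValueError("gains and noise scale must be >= 0")
        if not self.channels:
            raise ValueError("channel list must not be empty")


EMG_PROTOCOLS: dict[str, dict] = {
    "baseline": {"pulses": 1},
    "SICI2": {"pulses": 2, "isi_ms": 2.0},
    "SICI4": {"pulses": 2, "isi_ms": 4.0},
    "ICF10": {"pulses": 2, "isi_ms": 10.0},
    "ICF15": {"pulses": 2, "isi_ms": 15.0},
    "SICF3": {"pulses": 2, "isi_ms": 3.0},
    "LICI100": {"pulses": 2, "isi_ms": 100.0},
    "LICI220": {"pulses": 2, "isi_ms": 220.0},
    "CSP": {"pulses": 1},
    **{f"IO_{p}": {"pulses": 1, "intensity_pct_rmt": p} for p in range(100, 160, 10)},
}


@dataclass(frozen=True)
class EMGSimParams:
    """Controls for one synthetic EMG trial block."""

    protocol: str
    programmed_ratio: float = 1.0
    programmed_csp_ms: float = 150.0
    mep_amplitude_mv: float = 1.0
    noise_mv: float = 0.02
    n_trials: int = 15
    rate: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in EMG_PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; known: {sorted(EMG_PROTOCOLS)}"
            )
        if self.programmed_ratio <= 0:
            raise ValueError("programmed_ratio must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def make_chirp_stimulus(
    carrier_hz: float = 1000.0,
    am_f0: float = 0.0,
    am_f1: float = 120.0,
    duration_s: float = 2.0,
    rate: float = 44100.0,
) -> StimulusWaveform:
    """Carrier tone amplitude-modulated by a linear frequency sweep.

    The modulation envelope is ``(1 - cos(phi(t))) / 2`` with
    ``phi'(t)/2pi`` sweeping linearly from ``am_f0`` to ``am_f1``, so the
    envelope lies in [0, 1] and starts silent.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate <= 2 * carrier_hz:
        raise ValueError(
            f"rate {rate} Hz must exceed twice the carrier ({2 * carrier_hz} Hz)"
        )
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    # phase of a linear sweep: integral of f0 + (f1-f0) t / T
    phase = 2 * np.pi * (am_f0 * t + (am_f1 - am_f0) * t**2 / (2 * duration_s))
    envelope = 0.5 * (1.0 - np.cos(phase))
    samples = envelope * np.sin(2 * np.pi * carrier_hz * t)
    return StimulusWaveform(
        samples=samples,
        rate=rate,
        carrier_hz=carrier_hz,
        am_f0=am_f0,
        am_f1=am_f1,
        duration_s=duration_s,
    )


def make_trial_schedule(
    n_trials: int = 160,
    isi_bounds_ms: tuple[float, float] = (1500.0, 2500.0),
    stimulus_duration_s: float = 2.0,
    seed: int = 0,
    lead_in_s: float = 2.0,
) -> TrialSchedule:
    """Onset times with gaps (stimulus offset to next onset) drawn
    uniformly from ``isi_bounds_ms``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = isi_bounds_ms
    if lo > hi:
        raise ValueError(f"isi_bounds_ms must be ordered, got {isi_bounds_ms}")
    rng = np.random.default_rng(seed)
    gaps_s = rng.uniform(lo, hi, size=max(n_trials - 1, 0)) / 1000.0
    onsets = lead_in_s + np.concatenate(
        [[0.0], np.cumsum(gaps_s + stimulus_duration_s)]
    )
    return TrialSchedule(
        onsets=onsets,
        n_trials=n_trials,
        isi_bounds_ms=(lo, hi),
        stimulus_duration_s=stimulus_duration_s,
        seed=seed,
    )


def _one_over_f_noise(rng, n_samples: int, exponent: float, scale: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, SD = scale.

    Synthesised at an FFT-friendly length and truncated, purely for speed.
    """
    from scipy.fft import irfft, next_fast_len

    n_fft = next_fast_len(n_samples)
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    spectrum = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = irfft(spectrum, n=n_fft)[:n_samples]
    sd = x.std()
    if sd > 0:
        x = x * (scale / sd)
    return x


def _trial_phases(rng, kappa: float, n: int) -> np.ndarray:
    if kappa >= _KAPPA_PERFECT:
        return np.zeros(n)
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, size=n)
    return rng.vonmises(0.0, kappa, size=n)


def simulate_eeg_session(
    params: SimParams,
    schedule: TrialSchedule,
    stimulus: StimulusWaveform,
    rate: float = 1000.0,
    tail_s: float = 4.0,
) -> Recording:
    """Render a full synthetic EEG session at ``rate`` (default 1000 Hz).

    The entrained component oscillates at the stimulus AM instantaneous
    frequency (the envelope-following response, not the audio carrier),
    with trial-wise von Mises phase offsets; the onset burst is a
    Hann-windowed 0.5 s oscillation at ``onset_theta_freq``.  Stimulus
    onsets are embedded as ``"chirp"`` event markers.
    """
    if not params.channels:
        raise ValueError("empty channel list")
    rng = np.random.default_rng(params.seed)
    n_samples = int(round((schedule.session_duration_s + tail_s) * rate))
    if schedule.onsets[-1] + stimulus.duration_s > n_samples / rate:
        raise ValueError("schedule exceeds session length")
    n_ch = len(params.channels)
    data = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        data[c] = _one_over_f_noise(rng, n_samples, params.noise_exponent, params.noise_scale)

    # evoked components, shared across channels up to a regional gain
    n_trials = len(schedule.onsets)
    onset_phases = _trial_phases(rng, params.phase_locking_kappa, n_trials)
    entrain_phases = _trial_phases(rng, params.phase_locking_kappa, n_trials)

    dur = stimulus.duration_s
    n_stim = int(round(dur * rate))
    t_stim = np.arange(n_stim) / rate
    sweep_phase = 2 * np.pi * (
        stimulus.am_f0 * t_stim
        + (stimulus.am_f1 - stimulus.am_f0) * t_stim**2 / (2 * dur)
    )
    # soft edges so the entrained component does not click on/off
    edge = int(round(0.05 * rate))
    taper = np.ones(n_stim)
    if edge > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        taper[:edge] = ramp
        taper[-edge:] = ramp[::-1]

    n_burst = int(round(0.5 * rate))
    t_burst = np.arange(n_burst) / rate
    burst_window = np.hanning(n_burst)

    gains = np.array([_channel_gain(ch) for ch in params.channels])
    evoked = np.zeros(n_samples)
    for k, onset in enumerate(schedule.onsets):
        i0 = int(round(onset * rate))
        if params.onset_theta_gain > 0 and i0 + n_burst <= n_samples:
            evoked[i0 : i0 + n_burst] += (
                params.onset_theta_gain
                * burst_window
                * np.cos(2 * np.pi * params.onset_theta_freq * t_burst + onset_phases[k])
            )
        if params.entrain_gain > 0 and i0 + n_stim <= n_samples:
            evoked[i0 : i0 + n_stim] += (
                params.entrain_gain * taper * np.cos(sweep_phase + entrain_phases[k])
            )
    data += gains[:, None] * evoked[None, :]

    # blink-like artifacts: slow frontal transients beyond the +/-200 uV gate
    if params.artifact_rate_per_min > 0:
        n_art = rng.poisson(params.artifact_rate_per_min * n_samples / rate / 60.0)
        width = int(round(0.3 * rate))
        t_art = np.arange(width) / rate
        bump = np.exp(-0.5 * ((t_art - 0.15) / 0.05) ** 2)
        frontal = np.array(
            [1.0 if _channel_gain(ch) >= 0.9 else 0.2 for ch in params.channels]
        )
        for _ in range(n_art):
            i0 = rng.integers(0, max(n_samples - width, 1))
            amp = rng.uniform(300.0, 500.0)
            data[:, i0 : i0 + width] += frontal[:, None] * amp * bump[None, :]

    # bad channels: flatline (fails the low-SD gate downstream)
    for label in params.bad_channel_labels:
        if label in params.channels:
            c = params.channels.index(label)
            data[c] = 0.5 * rng.standard_normal(n_samples)

    events = [(float(t), "chirp") for t in schedule.onsets]
    return Recording(
        channel_names=list(params.channels),
        rate=rate,
        data=data,
        events=events,
        provenance=[
            f"synthetic session: group={params.group_label}, seed={params.seed}, "
            f"kappa={params.phase_locking_kappa}, entrain_gain={params.entrain_gain}"
        ],
    )


def _mep_waveform(rate: float, p2p_mv: float) -> np.ndarray:
    """Biphasic MEP-like deflection, ~20 ms latency, given peak-to-peak size."""
    n = int(round(0.040 * rate))
    t = np.arange(n) / rate
    w = np.sin(2 * np.pi * 60.0 * t) * np.exp(-0.5 * ((t - 0.008) / 0.004) ** 2)
    span = w.max() - w.min()
    return w * (p2p_mv / span)


def simulate_emg_trials(params: EMGSimParams) -> list:
    """Generate EMG trials for one TMS protocol.

    Returns a list of :class:`neurochirp.tms.EMGTrial`.  For paired-pulse
    protocols the (second) MEP realises ``programmed_ratio`` relative to
    ``mep_amplitude_mv`` on average; for CSP, a tonic contraction is
    silenced from shortly after the pulse until ``programmed_csp_ms``.
    """
    from .tms import EMGTrial  # deferred to avoid a cycle

    rng = np.random.default_rng(params.seed)
    spec = EMG_PROTOCOLS[params.protocol]
    rate = params.rate
    trials = []
    trial_var = 0.05  # 5 % multiplicative amplitude jitter

    for _ in range(params.n_trials):
        dur_s = 1.0
        n = int(round(dur_s * rate))
        trace = params.noise_mv * rng.standard_normal(n)
        jitter = 1.0 + trial_var * rng.standard_normal()

        if params.protocol == "CSP":
            pulse_t = 0.4
            # tonic contraction: band-limited EMG-like activity
            contraction = 0.15 * rng.standard_normal(n)
            i_pulse = int(round(pulse_t * rate))
            i_mep_end = i_pulse + int(round(0.030 * rate))
            i_return = i_pulse + int(round(params.programmed_csp_ms / 1000.0 * rate))
            silence = slice(i_mep_end, i_return)
            contraction[silence] = 0.0
            trace += contraction
            mep = _mep_waveform(rate, params.mep_amplitude_mv * jitter)
            i_mep = i_pulse + int(round(0.015 * rate))
            trace[i_mep : i_mep + len(mep)] += mep
            trials.append(
                EMGTrial(
                    trace=trace, rate=rate, pulse_times_s=(pulse_t,),
                    protocol="CSP", intensity_pct_rmt=125.0,
                )
            )
            continue

        if spec["pulses"] == 1:
            pulse_times = (0.2,)
            amp1 = params.mep_amplitude_mv * jitter
            mep = _mep_waveform(rate, amp1)
            i_mep = int(round((0.2 + 0.018) * rate))
            trace[i_mep : i_mep + len(mep)] += mep
        else:
            isi_s = spec["isi_ms"] / 1000.0
            pulse_times = (0.2, 0.2 + isi_s)
            if params.protocol.startswith("LICI"):
                # both pulses suprathreshold: two MEPs, second scaled
                amp1 = params.mep_amplitude_mv * jitter
                amp2 = params.mep_amplitude_mv * params.programmed_ratio * (
                    1.0 + trial_var * rng.standard_normal()
                )
                for pt, amp in zip(pulse_times, (amp1, amp2)):
                    mep = _mep_waveform(rate, amp)
                    i_mep = int(round((pt + 0.018) * rate))
                    trace[i_mep : i_mep + len(mep)] += mep
            else:
                # subthreshold conditioning pulse: single modulated MEP after TS
                amp = params.mep_amplitude_mv * params.programmed_ratio * jitter
                mep = _mep_waveform(rate, amp)
                i_mep = int(round((pulse_times[1] + 0.018) * rate))
                trace[i_mep : i_mep + len(mep)] += mep

        trials.append(
            EMGTrial(
                trace=trace,
                rate=rate,
                pulse_times_s=pulse_times,
                protocol=params.protocol,
                intensity_pct_rmt=float(spec.get("intensity_pct_rmt", 125)),
            )
        )
    return trials
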