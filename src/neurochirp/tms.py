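"""TMS-EMG outcome measures: peak-to-peak MEPs, paired-pulse ratios,
per-trial LICI ratios, cortical silent period, and input/output curves.

Operational choices not fixed by convention are exposed as parameters
and recorded in outputs:

* MEP search window 15-60 ms after the (relevant) pulse;
* CSP: rectified EMG smoothed with a 5 ms moving average; "return to
  baseline" is the first instant exceeding 50 % of the mean pre-pulse
  rectified amplitude sustained for >= 10 ms;
* LICI trials whose first MEP is below 3x the pre-pulse noise SD are
  excluded (noise-floor guard against division blow-ups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EMGTrial",
    "MEPMeasure",
    "MEP_WINDOW_S",
    "peak_to_peak",
    "paired_pulse_ratio",
    "lici_ratio",
    "csp_duration",
    "io_curve",
    "summarize_protocols",
]

MEP_WINDOW_S: tuple[float, float] = (0.015, 0.060)


@dataclass(frozen=True)
class EMGTrial:
    """One EMG sweep with its TMS pulse timestamps."""

    trace: np.ndarray
    rate: float
    pulse_times_s: tuple[float, ...]
    protocol: str = ""
    intensity_pct_rmt: float = 125.0

    def __post_init__(self) -> None:
        if list(self.pulse_times_s) != sorted(self.pulse_times_s):
            raise ValueError("pulse times must be ascending")


@dataclass(frozen=True)
class MEPMeasure:
    p2p_amplitude: float
    search_window_s: tuple[float, float]


def peak_to_peak(
    trial: EMGTrial,
    window_s: tuple[float, float] = MEP_WINDOW_S,
    pulse_index: int = -1,
) -> MEPMeasure:
    """Max minus min of the trace inside ``window_s`` after a pulse.

    ``pulse_index`` selects which pulse the window is anchored to
    (default: the last one, i.e. the test stimulus).
    """
    pulse_t = trial.pulse_times_s[pulse_index]
    i0 = int(round((pulse_t + window_s[0]) * trial.rate))
    i1 = int(round((pulse_t + window_s[1]) * trial.rate))
    if i0 < 0 or i1 > len(trial.trace):
        raise ValueError(
            f"MEP window {window_s} s after pulse at {pulse_t} s falls outside the trace"
        )
    seg = trial.trace[i0:i1]
    return MEPMeasure(float(seg.max() - seg.min()), window_s)


def paired_pulse_ratio(
    conditioned_trials: list[EMGTrial],
    baseline_trials: list[EMGTrial],
    window_s: tuple[float, float] = MEP_WINDOW_S,
) -> float:
    """mean(conditioned MEP p2p) / mean(baseline MEP p2p).

    Values < 1 indicate inhibition, > 1 facilitation.
    """
    if not conditioned_trials or not baseline_trials:
        raise ValueError("need at least one trial in each set")
    cond = np.mean([peak_to_peak(t, window_s).p2p_amplitude for t in conditioned_trials])
    base = np.mean([peak_to_peak(t, window_s).p2p_amplitude for t in baseline_trials])
    if base <= 0:
        raise ValueError("baseline mean MEP amplitude is zero")
    return float(cond / base)


def _prepulse_noise_sd(trial: EMGTrial, margin_s: float = 0.005) -> float:
    i_end = int(round((trial.pulse_times_s[0] - margin_s) * trial.rate))
    if i_end <= 1:
        return 0.0
    return float(trial.trace[:i_end].std())


def lici_ratio(
    trials: list[EMGTrial],
    window_s: tuple[float, float] = MEP_WINDOW_S,
    noise_floor_mult: float = 3.0,
) -> tuple[float, list[int]]:
    """Per-trial (second MEP)/(first MEP) ratios, averaged.

    Trials whose first MEP fails the noise-floor check
    (p2p < ``noise_floor_mult`` x pre-pulse noise SD) are excluded;
    their indices are returned alongside the mean ratio.
    """
    if not trials:
        raise ValueError("no trials given")
    ratios, excluded = [], []
    for i, trial in enumerate(trials):
        if len(trial.pulse_times_s) != 2:
            raise ValueError(f"trial {i}: LICI requires exactly 2 pulses")
        first = peak_to_peak(trial, window_s, pulse_index=0).p2p_amplitude
        second = peak_to_peak(trial, window_s, pulse_index=1).p2p_amplitude
        floor = noise_floor_mult * _prepulse_noise_sd(trial)
        if first <= floor:
            excluded.append(i)
            continue
        ratios.append(second / first)
    if not ratios:
        raise ValueError("every trial excluded by the first-MEP noise floor")
    return float(np.mean(ratios)), excluded


def _smooth_rectified(trace: np.ndarray, rate: float, smooth_s: float = 0.005) -> np.ndarray:
    w = max(int(round(smooth_s * rate)), 1)
    kernel = np.ones(w) / w
    return np.convolve(np.abs(trace), kernel, mode="same")


def _first_sustained(mask: np.ndarray, min_run: int) -> int | None:
    """Index of the first run of True at least ``min_run`` long."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return None
    # run-length encode the True indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_run:
            return int(s)
    return None


def csp_duration(
    trial: EMGTrial,
    baseline_window_s: tuple[float, float] | None = None,
    criterion_frac: float = 0.5,
    sustain_ms: float = 10.0,
    smooth_s: float = 0.005,
    contraction_floor: float = 0.01,
) -> tuple[float, bool]:
    """Cortical silent period: ms from the pulse to EMG return.

    The rectified trace is smoothed (moving average, ``smooth_s``); the
    silent period ends at the first instant where it re-exceeds
    ``criterion_frac`` of the mean pre-pulse rectified amplitude for a
    sustained run of ``sustain_ms``.  Returns ``(duration_ms, short)``
    where ``short`` flags the absence of any detectable silence (the
    returned time is then just the MEP offset).

    Raises
    ------
    ValueError
        If no tonic pre-pulse contraction is present (CSP undefined).
    """
    pulse_t = trial.pulse_times_s[0]
    i_pulse = int(round(pulse_t * trial.rate))
    if baseline_window_s is None:
        baseline_window_s = (0.0, max(pulse_t - 0.01, 0.0))
    b0 = int(round(baseline_window_s[0] * trial.rate))
    b1 = int(round(baseline_window_s[1] * trial.rate))
    smoothed = _smooth_rectified(trial.trace, trial.rate, smooth_s)
    baseline = float(smoothed[b0:b1].mean()) if b1 > b0 else 0.0
    if baseline < contraction_floor:
        raise ValueError(
            f"no pre-pulse contraction (rectified baseline {baseline:.4f} below "
            f"floor {contraction_floor}); CSP undefined"
        )
    criterion = criterion_frac * baseline
    min_run = max(int(round(sustain_ms / 1000.0 * trial.rate)), 1)
    post = smoothed[i_pulse:]

    silent_start = _first_sustained(post < criterion, min_run)
    if silent_start is None:
        # EMG never goes quiet: report the MEP offset (first return of the
        # smoothed envelope to the pre-pulse level after the MEP peak),
        # flagged short
        search = post[: int(round(0.080 * trial.rate))]
        peak = int(np.argmax(search)) if len(search) else 0
        after = np.flatnonzero(post[peak:] <= baseline)
        offset = peak + int(after[0]) if len(after) else len(post) - 1
        return offset / trial.rate * 1000.0, True
    ret = _first_sustained(post[silent_start:] >= criterion, min_run)
    if ret is None:
        return (len(post) - 1) / trial.rate * 1000.0, True
    return (silent_start + ret) / trial.rate * 1000.0, False


def io_curve(
    trials_by_intensity: dict[int, list[EMGTrial]],
    window_s: tuple[float, float] = MEP_WINDOW_S,
) -> pd.DataFrame:
    """Input/output curve: mean +/- SD peak-to-peak MEP per intensity.

    Keys are stimulus intensities in % of resting motor threshold.
    """
    if not trials_by_intensity:
        raise ValueError("need at least one intensity level")
    rows = []
    for intensity in sorted(trials_by_intensity):
        try:
            pct = float(intensity)
        except (TypeError, ValueError):
            raise ValueError(f"unknown intensity label {intensity!r}") from None
        amps = [
            peak_to_peak(t, window_s).p2p_amplitude
            for t in trials_by_intensity[intensity]
        ]
        rows.append(
            {
                "intensity_pct_rmt": pct,
                "mean_p2p": float(np.mean(amps)),
                "sd_p2p": float(np.std(amps, ddof=1)) if len(amps) > 1 else 0.0,
                "n_trials": len(amps),
            }
        )
    return pd.DataFrame(rows).sort_values("intensity_pct_rmt", ignore_index=True)


def summarize_protocols(
    trials_by_protocol: dict[str, list[EMGTrial]],
    subject_id: str = "",
    window_s: tuple[float, float] = MEP_WINDOW_S,
) -> pd.DataFrame:
    """Per-protocol summary table for one subject.

    Paired protocols (SICI/ICF/SICF) are expressed over the ``baseline``
    block; LICI protocols use within-trial ratios; ``CSP`` reports the
    mean detected duration; ``IO_*`` blocks report mean p2p.
    """
    baseline = trials_by_protocol.get("baseline")
    rows = []
    for protocol, trials in trials_by_protocol.items():
        row = {"subject_id": subject_id, "protocol": protocol, "n_trials": len(trials)}
        if protocol == "baseline":
            row["value"] = float(
                np.mean([peak_to_peak(t, window_s).p2p_amplitude for t in trials])
            )
            row["measure"] = "mean_p2p_mv"
        elif protocol.startswith("LICI"):
            value, excluded = lici_ratio(trials, window_s)
            row["value"] = value
            row["measure"] = "ratio"
            row["n_excluded"] = len(excluded)
        elif protocol == "CSP":
            durations = [csp_duration(t)[0] for t in trials]
            row["value"] = float(np.mean(durations))
            row["measure"] = "csp_ms"
        elif protocol.startswith("IO_"):
            row["value"] = float(
                np.mean([peak_to_peak(t, window_s).p2p_amplitude for t in trials])
            )
            row["measure"] = "mean_p2p_mv"
        else:
            if baseline is None:
                raise ValueError(f"protocol {protocol!r} needs a 'baseline' block")
            row["value"] = paired_pulse_ratio(trials, baseline, window_s)
            row["measure"] = "ratio"
        rows.append(row)
    return pd.DataFrame(rows)
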