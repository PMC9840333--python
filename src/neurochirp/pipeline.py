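"""Convenience drivers chaining simulate -> preprocess -> time-frequency
-> extraction for one subject or one whole synthetic study.

These exist so calibration experiments (null ITC floor, parameter
recovery, group-difference power) can be written as a few lines, and so
the CLI and the test-suite exercise exactly the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import masks as masks_mod
from . import preprocess as pre
from . import stats as stats_mod
from . import synth, tfr

__all__ = ["subject_itc", "subject_maps", "run_group_study"]


def _preprocess_to_roi(
    recording: pre.Recording,
    onsets: np.ndarray,
    roi: str,
    tmin: float = -1.0,
    tmax: float = 3.5,
) -> pre.EpochSet:
    filtered = pre.bandpass_notch(recording)
    cleaned, _removed = pre.reject_channels_by_sd(filtered)
    epochs = pre.epoch(cleaned, onsets, tmin=tmin, tmax=tmax)
    epochs = pre.reject_epochs_by_amplitude(epochs)
    return pre.roi_average(epochs, pre.ROI_DEFINITIONS[roi])


def subject_itc(
    params: synth.SimParams,
    schedule: synth.TrialSchedule,
    stimulus: synth.StimulusWaveform,
    roi: str = "Fz",
    freqs_hz: np.ndarray | None = None,
    decim: int = 10,
) -> tfr.ITCMap:
    """Simulate one subject and return the ROI ITC map (full chain)."""
    recording = synth.simulate_eeg_session(params, schedule, stimulus)
    roi_epochs = _preprocess_to_roi(recording, schedule.onsets, roi)
    tf = tfr.morlet_tf(roi_epochs, freqs_hz=freqs_hz, decim=decim)
    return tfr.itc(tf)


def subject_maps(
    params: synth.SimParams,
    schedule: synth.TrialSchedule,
    stimulus: synth.StimulusWaveform,
    rois: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz"),
    freqs_hz: np.ndarray | None = None,
    decim: int = 10,
    baseline_window_s: tuple[float, float] = (-0.8, -0.2),
) -> dict:
    """Simulate one subject; ERSP and ITC maps for each requested ROI."""
    recording = synth.simulate_eeg_session(params, schedule, stimulus)
    out = {}
    for roi in rois:
        roi_epochs = _preprocess_to_roi(recording, schedule.onsets, roi)
        tf = tfr.morlet_tf(roi_epochs, freqs_hz=freqs_hz, decim=decim)
        out[roi] = {"ERSP_db": tfr.ersp(tf, baseline_window_s), "ITC": tfr.itc(tf)}
    return out


def run_group_study(
    n_control: int = 21,
    n_carrier: int = 8,
    control_kappa: float = 0.8,
    carrier_kappa: float = 8.0,
    n_trials: int = 40,
    entrain_gain: float = 8.0,
    carrier_gain: float | None = 30.0,
    noise_scale: float = 20.0,
    freqs_hz: np.ndarray | None = None,
    band: str = "low_gamma",
    roi: str = "Fz",
    seed: int = 0,
    decim: int = 10,
    frontal_only: bool = True,
) -> pd.DataFrame:
    """One synthetic two-group study, returning per-subject within-mask
    ITC band summaries ready for ANOVA.

    Each subject is simulated and run through the full chain; the
    entrainment mask is built from the pooled (all-subjects) mean frontal
    ITC map, then applied per subject.  ``frontal_only`` restricts the
    montage to the frontal ROI electrodes for speed.
    """
    if freqs_hz is None:
        lo, hi = masks_mod.BAND_DEFINITIONS[band].range_hz
        freqs_hz = np.arange(lo, hi + 1, 2.0)
    rng = np.random.default_rng(seed)
    stimulus = synth.make_chirp_stimulus()
    channels = (
        pre.ROI_DEFINITIONS[roi].electrodes
        if frontal_only
        else synth.DEFAULT_CHANNELS
    )

    if carrier_gain is None:
        carrier_gain = entrain_gain
    rows = []
    itc_maps = []
    for group, kappa, gain, n_sub in (
        ("control", control_kappa, entrain_gain, n_control),
        ("carrier", carrier_kappa, carrier_gain, n_carrier),
    ):
        for i in range(n_sub):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            schedule = synth.make_trial_schedule(n_trials=n_trials, seed=sub_seed)
            params = synth.SimParams(
                group_label=group,
                channels=channels,
                phase_locking_kappa=kappa,
                entrain_gain=gain,
                onset_theta_gain=0.0,
                noise_scale=noise_scale,
                seed=sub_seed,
            )
            itc_map = subject_itc(
                params, schedule, stimulus, roi=roi, freqs_hz=freqs_hz, decim=decim
            )
            itc_maps.append(itc_map)
            rows.append({"subject_id": f"{group}_{i:02d}", "group": group})

    pooled = itc_maps[0]
    pooled_values = np.mean([m.values for m in itc_maps], axis=0)
    pooled_map = tfr.ITCMap(
        values=pooled_values,
        freqs_hz=pooled.freqs_hz,
        times_s=pooled.times_s,
        n_trials=pooled.n_trials,
        valid_mask=np.logical_and.reduce([m.valid_mask for m in itc_maps]),
    )
    _onset, entrain_mask = masks_mod.build_masks(pooled_map)
    band_def = masks_mod.BAND_DEFINITIONS[band]
    for row, itc_map in zip(rows, itc_maps):
        value, n_cells = masks_mod.band_summary(itc_map, entrain_mask, band_def)
        row.update({"band": band, "measure": "ITC", "value": value, "n_cells": n_cells})
    return pd.DataFrame(rows)


def study_anova_p(summaries: pd.DataFrame) -> float:
    """One-way ANOVA p-value over the groups of a study summary table."""
    values_by_group = {
        g: sub["value"].to_numpy() for g, sub in summaries.groupby("group")
    }
    return stats_mod.oneway_anova(values_by_group).p
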