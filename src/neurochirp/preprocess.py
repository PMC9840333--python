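"""EEG cleaning chain: filtering, channel rejection, epoching, amplitude
rejection and ROI averaging.

The chain operates on :class:`Recording` objects (continuous multi-channel
data in microvolts) and produces :class:`EpochSet` objects (trials x
channels x time).  Every destructive step appends to the provenance /
rejection logs so the full history of a dataset is auditable.

Notes on unit conventions
-------------------------
Channel standard-deviation rejection bounds default to 2 and 120 and are
interpreted in **microvolts**: scalp EEG never spans millivolts, so
millivolt-labelled bounds in acquisition reports are treated as a units
typo.  This interpretation is deliberate and surfaced here rather than
hidden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "ROIDefinition",
    "ROI_DEFINITIONS",
    "bandpass_notch",
    "reject_channels_by_sd",
    "epoch",
    "reject_epochs_by_amplitude",
    "roi_average",
]


@dataclass
class Recording:
    """Continuous multi-channel EEG/EMG data.

    Parameters
    ----------
    channel_names : list of str
        Unique channel labels (10-10 names for EEG).
    rate : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Samples in microvolts.
    events : list of (float, str)
        Event markers as ``(time_s, label)`` pairs.
    provenance : list of str
        Human-readable record of processing steps applied so far.
    """

    channel_names: list[str]
    rate: float
    data: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        dur = self.data.shape[1] / self.rate
        for t, label in self.events:
            if not (0.0 <= t <= dur):
                raise ValueError(f"event {label!r} at {t} s outside record [0, {dur}] s")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.rate

    def copy_with(self, **kwargs) -> "Recording":
        out = dataclasses.replace(self, **kwargs)
        return out


@dataclass
class EpochSet:
    """Retained trials x channels x samples, plus the rejection bookkeeping.

    ``retained_flags`` always has one entry per *originally scheduled* epoch
    so that retained + rejected + out-of-range == scheduled, by construction.
    """

    data: np.ndarray
    channel_names: list[str]
    rate: float
    tmin_s: float
    tmax_s: float
    retained_flags: np.ndarray
    rejection_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.retained_flags = np.asarray(self.retained_flags, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        n_expected = int(round((self.tmax_s - self.tmin_s) * self.rate))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != round((tmax-tmin)*rate)={n_expected}"
            )
        if int(self.retained_flags.sum()) != self.data.shape[0]:
            raise ValueError("retained_flags inconsistent with epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def onset_index(self) -> int:
        """Sample index of t = 0 within each epoch."""
        return int(round(-self.tmin_s * self.rate))

    @property
    def times_s(self) -> np.ndarray:
        """Epoch-relative time axis, half-open [tmin, tmax)."""
        return self.tmin_s + np.arange(self.data.shape[2]) / self.rate


@dataclass(frozen=True)
class ROIDefinition:
    """A named scalp region of interest: an average over listed electrodes."""

    name: str
    electrodes: tuple[str, ...]


#: The four study ROIs (frontal, central, parietal, occipital).
ROI_DEFINITIONS: dict[str, ROIDefinition] = {
    "Fz": ROIDefinition("Fz", ("F3", "F1", "Fz", "F2", "F4")),
    "Cz": ROIDefinition("Cz", ("C1", "Cz", "C2", "FC1", "FCz", "FC2")),
    "Pz": ROIDefinition("Pz", ("P3", "P1", "Pz", "P2", "P4")),
    "Oz": ROIDefinition("Oz", ("O1", "Oz", "O2", "PO3", "POz", "PO4")),
}


def bandpass_notch(
    recording: Recording,
    band: tuple[float, float] = (0.5, 150.0),
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase bandpass + notch filter.

    A 4th-order Butterworth bandpass and a 2nd-order IIR notch (quality
    ``notch_q``), both applied forward-backward (``filtfilt``) for zero
    phase distortion.

    Raises
    ------
    ValueError
        If the band's upper edge is not below Nyquist.
    """
    lo, hi = band
    nyq = recording.rate / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got {band}")
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyq} Hz")

    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=recording.rate, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    steps = [f"bandpass {lo}-{hi} Hz (butter4, zero-phase)"]
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch {notch} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(notch, notch_q, fs=recording.rate)
        out = signal.filtfilt(b, a, out, axis=1)
        steps.append(f"notch {notch} Hz (Q={notch_q}, zero-phase)")
    return recording.copy_with(
        data=out, provenance=recording.provenance + steps
    )


def reject_channels_by_sd(
    recording: Recording, lo: float = 2.0, hi: float = 120.0
) -> tuple[Recording, list[str]]:
    """Drop channels whose sample standard deviation falls outside [lo, hi].

    Bounds are in microvolts (see module docstring on the units decision).
    Returns the reduced recording and the removed labels.

    Raises
    ------
    ValueError
        If the recording has no channels, or if every channel is removed.
    """
    if recording.n_channels == 0:
        raise ValueError("recording has no channels")
    sds = recording.data.std(axis=1)
    keep = (sds >= lo) & (sds <= hi)
    removed = [name for name, k in zip(recording.channel_names, keep) if not k]
    if not keep.any():
        raise ValueError("all channels rejected by SD criterion; recording unusable")
    kept_names = [name for name, k in zip(recording.channel_names, keep) if k]
    out = recording.copy_with(
        channel_names=kept_names,
        data=recording.data[keep],
        provenance=recording.provenance
        + [f"channel SD rejection [{lo}, {hi}] uV: removed {removed}"],
    )
    return out, removed


def epoch(
    recording: Recording,
    onsets_s: np.ndarray,
    tmin: float = -1.0,
    tmax: float = 3.5,
) -> EpochSet:
    """Cut one epoch per onset, half-open window [tmin, tmax).

    Onsets whose window does not fit entirely inside the recording are
    dropped and logged (their ``retained_flags`` entry is False).

    Raises
    ------
    ValueError
        If ``tmin >= 0`` or ``tmax <= 0``, or if no epoch can be extracted.
    """
    if not (tmin < 0 < tmax):
        raise ValueError(f"need tmin < 0 < tmax, got ({tmin}, {tmax})")
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    n_len = int(round((tmax - tmin) * recording.rate))
    starts = np.round((onsets_s + tmin) * recording.rate).astype(int)
    ok = (starts >= 0) & (starts + n_len <= recording.n_samples)
    log = []
    for t, good in zip(onsets_s, ok):
        if not good:
            log.append(f"onset {t:.3f} s: epoch window outside recording, dropped")
    if not ok.any():
        raise ValueError("no epoch fits inside the recording")
    data = np.stack([recording.data[:, s : s + n_len] for s in starts[ok]])
    return EpochSet(
        data=data,
        channel_names=list(recording.channel_names),
        rate=recording.rate,
        tmin_s=tmin,
        tmax_s=tmax,
        retained_flags=ok,
        rejection_log=log,
    )


def reject_epochs_by_amplitude(epochs: EpochSet, thresh_uv: float = 200.0) -> EpochSet:
    """Remove epochs containing any sample strictly beyond +/- ``thresh_uv``.

    The comparison is strict (a sample exactly at the threshold is kept),
    matching a "greater than" tagging rule.

    Raises
    ------
    ValueError
        If the threshold is not positive or no epoch survives.
    """
    if thresh_uv <= 0:
        raise ValueError("threshold must be positive")
    bad = np.abs(epochs.data) > thresh_uv
    keep = ~bad.any(axis=(1, 2))
    if not keep.any():
        raise ValueError("no epoch survives amplitude rejection")
    # map back onto the original schedule-length flag vector
    flags = epochs.retained_flags.copy()
    retained_idx = np.flatnonzero(flags)
    flags[retained_idx[~keep]] = False
    n_rej = int((~keep).sum())
    log = epochs.rejection_log + [
        f"amplitude rejection +/-{thresh_uv} uV: removed {n_rej} of {epochs.n_epochs}"
    ]
    return EpochSet(
        data=epochs.data[keep],
        channel_names=list(epochs.channel_names),
        rate=epochs.rate,
        tmin_s=epochs.tmin_s,
        tmax_s=epochs.tmax_s,
        retained_flags=flags,
        rejection_log=log,
    )


def roi_average(epochs: EpochSet, roi_def: ROIDefinition) -> EpochSet:
    """Average the surviving electrodes of a ROI into one virtual channel.

    Raises
    ------
    ValueError
        If none of the ROI electrodes survive in ``epochs``.
    """
    present = [ch for ch in roi_def.electrodes if ch in epochs.channel_names]
    if not present:
        raise ValueError(
            f"ROI {roi_def.name!r}: none of {roi_def.electrodes} present in epochs"
        )
    idx = [epochs.channel_names.index(ch) for ch in present]
    mean = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    log = epochs.rejection_log + [
        f"ROI {roi_def.name}: averaged over {present}"
    ]
    return EpochSet(
        data=mean,
        channel_names=[roi_def.name],
        rate=epochs.rate,
        tmin_s=epochs.tmin_s,
        tmax_s=epochs.tmax_s,
        retained_flags=epochs.retained_flags,
        rejection_log=log,
    )
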