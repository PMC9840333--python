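"""Serialization: flat little-endian float32 binary + JSON sidecar for
recordings and maps, WAV export for stimuli, CSV for schedules and
tables.

The container for a recording named ``foo`` is the pair ``foo.f32``
(channel-major float32 samples) and ``foo.json`` (channel names, rate,
events, provenance).  Maps use the same pattern with the grid axes in
the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import Recording
from .synth import StimulusWaveform, TrialSchedule
from .tfr import ERSPMap, ITCMap

__all__ = [
    "save_recording",
    "load_recording",
    "save_stimulus_wav",
    "save_schedule_csv",
    "load_schedule_csv",
    "save_map",
    "load_map",
    "map_to_long_csv",
]


def save_recording(recording: Recording, basename: str | Path) -> tuple[Path, Path]:
    base = Path(basename)
    raw_path = base.with_suffix(".f32")
    meta_path = base.with_suffix(".json")
    recording.data.astype("<f4").tofile(raw_path)
    meta = {
        "channel_names": recording.channel_names,
        "rate": recording.rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "units": "uV",
        "dtype": "<f4",
        "order": "channel-major",
        "events": [[t, label] for t, label in recording.events],
        "provenance": recording.provenance,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return raw_path, meta_path


def load_recording(basename: str | Path) -> Recording:
    base = Path(basename)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.fromfile(base.with_suffix(".f32"), dtype="<f4").astype(float)
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    return Recording(
        channel_names=meta["channel_names"],
        rate=meta["rate"],
        data=data,
        events=[(float(t), str(label)) for t, label in meta["events"]],
        provenance=list(meta.get("provenance", [])),
    )


def save_stimulus_wav(stimulus: StimulusWaveform, path: str | Path) -> Path:
    path = Path(path)
    scaled = np.clip(stimulus.samples, -1.0, 1.0)
    wavfile.write(path, int(stimulus.rate), (scaled * 32767).astype(np.int16))
    return path


def save_schedule_csv(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    gaps_ms = np.full(len(schedule.onsets), np.nan)
    if len(schedule.onsets) > 1:
        gaps_ms[1:] = (
            np.diff(schedule.onsets) - schedule.stimulus_duration_s
        ) * 1000.0
    pd.DataFrame({"onset_s": schedule.onsets, "isi_ms": gaps_ms}).to_csv(
        path, index=False
    )
    return path


def load_schedule_csv(path: str | Path) -> np.ndarray:
    """Onset times only; enough to drive epoching."""
    return pd.read_csv(path)["onset_s"].to_numpy()


def save_map(tfmap: ERSPMap | ITCMap, basename: str | Path) -> tuple[Path, Path]:
    base = Path(basename)
    raw_path = base.with_suffix(".f32")
    meta_path = base.with_suffix(".json")
    values = tfmap.values_db if isinstance(tfmap, ERSPMap) else tfmap.values
    values.astype("<f4").tofile(raw_path)
    meta = {
        "kind": "ERSP_db" if isinstance(tfmap, ERSPMap) else "ITC",
        "freqs_hz": tfmap.freqs_hz.tolist(),
        "times_s": tfmap.times_s.tolist(),
        "n_trials": tfmap.n_trials,
        "valid_mask": tfmap.valid_mask.astype(int).tolist(),
        "meta": tfmap.meta,
    }
    if isinstance(tfmap, ERSPMap):
        meta["baseline_window_s"] = list(tfmap.baseline_window_s)
    meta_path.write_text(json.dumps(meta, indent=2))
    return raw_path, meta_path


def load_map(basename: str | Path) -> ERSPMap | ITCMap:
    base = Path(basename)
    meta = json.loads(base.with_suffix(".json").read_text())
    freqs = np.array(meta["freqs_hz"])
    times = np.array(meta["times_s"])
    values = (
        np.fromfile(base.with_suffix(".f32"), dtype="<f4")
        .astype(float)
        .reshape(len(freqs), len(times))
    )
    valid = np.array(meta["valid_mask"], dtype=bool)
    if meta["kind"] == "ERSP_db":
        return ERSPMap(
            values_db=values,
            freqs_hz=freqs,
            times_s=times,
            baseline_window_s=tuple(meta["baseline_window_s"]),
            n_trials=meta["n_trials"],
            valid_mask=valid,
            meta=meta.get("meta", {}),
        )
    return ITCMap(
        values=values,
        freqs_hz=freqs,
        times_s=times,
        n_trials=meta["n_trials"],
        valid_mask=valid,
        meta=meta.get("meta", {}),
    )


def map_to_long_csv(tfmap: ERSPMap | ITCMap, roi: str, path: str | Path) -> Path:
    """Long-format (roi, freq_hz, time_s, value) CSV for interoperability."""
    path = Path(path)
    values = tfmap.values_db if isinstance(tfmap, ERSPMap) else tfmap.values
    ff, tt = np.meshgrid(tfmap.freqs_hz, tfmap.times_s, indexing="ij")
    pd.DataFrame(
        {
            "roi": roi,
            "freq_hz": ff.ravel(),
            "time_s": tt.ravel(),
            "value": values.ravel(),
        }
    ).to_csv(path, index=False)
    return path
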