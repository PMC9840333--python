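"""Onset / entrainment masks from the frontal ITC map, and within-mask
band summaries of ERSP and ITC maps.

The masks are built once from the whole-sample mean frontal ITC map
(threshold inclusive: cell kept when ITC >= threshold) and then applied
to every subject and ROI.  The onset mask lives in 0-500 ms, the
entrainment mask in 750-2250 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .tfr import ERSPMap, ITCMap

__all__ = [
    "AnalysisMask",
    "BandDefinition",
    "BAND_DEFINITIONS",
    "build_masks",
    "band_summary",
    "extract_all",
]


@dataclass
class AnalysisMask:
    """Boolean frequency x time selection tied to a fixed analysis window."""

    kind: str  # "onset" | "entrainment"
    window_s: tuple[float, float]
    threshold: float
    cells: np.ndarray  # (n_freqs, n_times) bool
    freqs_hz: np.ndarray
    times_s: np.ndarray
    source: str = ""

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band applicable to one of the two masks."""

    name: str
    range_hz: tuple[float, float]
    applicable_mask: str  # "onset" | "entrainment"


#: Study bands: low-frequency bands on the onset mask, gamma on entrainment.
BAND_DEFINITIONS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", (3.0, 8.0), "onset"),
    "alpha": BandDefinition("alpha", (8.0, 14.0), "onset"),
    "beta": BandDefinition("beta", (14.0, 17.0), "onset"),
    "low_gamma": BandDefinition("low_gamma", (30.0, 55.0), "entrainment"),
    "high_gamma": BandDefinition("high_gamma", (65.0, 100.0), "entrainment"),
}


def build_masks(
    frontal_itc_map: ITCMap,
    threshold: float = 0.13,
    onset_window: tuple[float, float] = (0.0, 0.5),
    entrain_window: tuple[float, float] = (0.75, 2.25),
    source: str = "whole-sample mean frontal ITC",
) -> tuple[AnalysisMask, AnalysisMask]:
    """Threshold the frontal ITC map inside the two fixed time windows.

    A cell is selected when ``ITC >= threshold`` (inclusive), it lies
    inside the window, and it is valid (edge-free).
    """
    times = frontal_itc_map.times_s
    masks = []
    for kind, (w0, w1) in (("onset", onset_window), ("entrainment", entrain_window)):
        if w0 < times[0] or w1 > times[-1] + 1e-9:
            raise ValueError(
                f"{kind} window {w0}-{w1} s outside map extent "
                f"[{times[0]:.3f}, {times[-1]:.3f}] s"
            )
        in_window = (times >= w0) & (times <= w1)
        cells = (
            (frontal_itc_map.values >= threshold)
            & in_window[None, :]
            & frontal_itc_map.valid_mask
        )
        masks.append(
            AnalysisMask(
                kind=kind,
                window_s=(w0, w1),
                threshold=threshold,
                cells=cells,
                freqs_hz=frontal_itc_map.freqs_hz,
                times_s=times,
                source=source,
            )
        )
    return masks[0], masks[1]


def band_summary(
    tfmap: ERSPMap | ITCMap,
    mask: AnalysisMask,
    band_def: BandDefinition,
) -> tuple[float, int]:
    """Mean of map cells inside ``mask`` with frequency in the band range.

    Returns ``(value, n_cells)``.  With zero masked cells in the band the
    value is NaN and a warning is emitted (never a silent zero).  Band
    edges are half-open ``[lo, hi)`` so adjacent bands do not overlap.
    """
    if band_def.applicable_mask != mask.kind:
        raise ValueError(
            f"band {band_def.name!r} applies to the {band_def.applicable_mask} "
            f"mask, got a {mask.kind} mask"
        )
    values = tfmap.values_db if isinstance(tfmap, ERSPMap) else tfmap.values
    if values.shape != mask.cells.shape:
        raise ValueError("map and mask grids differ in shape")
    lo, hi = band_def.range_hz
    in_band = (tfmap.freqs_hz >= lo) & (tfmap.freqs_hz < hi)
    cells = mask.cells & in_band[:, None]
    n = int(cells.sum())
    if n == 0:
        warnings.warn(
            f"no masked cells for band {band_def.name!r} in the {mask.kind} mask; "
            "summary undefined",
            stacklevel=2,
        )
        return float("nan"), 0
    return float(values[cells].mean()), n


def extract_all(
    subject_maps: dict,
    masks: tuple[AnalysisMask, AnalysisMask],
    band_defs: dict[str, BandDefinition] | None = None,
    roi_list: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz"),
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format table of within-mask band summaries for every subject.

    Parameters
    ----------
    subject_maps : dict
        ``subject_maps[subject_id][roi]`` is a dict with keys
        ``"ERSP_db"`` (an :class:`ERSPMap`) and ``"ITC"`` (an
        :class:`ITCMap`).
    masks : (onset_mask, entrainment_mask)
        The shared masks built from the pooled frontal ITC map.
    groups : dict, optional
        Subject id -> group label.

    Returns
    -------
    DataFrame with columns
    (subject_id, group, roi, band, measure, value, n_cells).
    """
    if band_defs is None:
        band_defs = BAND_DEFINITIONS
    mask_by_kind = {m.kind: m for m in masks}
    rows = []
    for subject_id, rois in subject_maps.items():
        group = (groups or {}).get(subject_id, "")
        for roi in roi_list:
            if roi not in rois:
                raise ValueError(f"subject {subject_id!r} is missing maps for ROI {roi!r}")
            for measure in ("ERSP_db", "ITC"):
                if measure not in rois[roi]:
                    raise ValueError(
                        f"subject {subject_id!r}, ROI {roi!r}: missing {measure} map"
                    )
            for band in band_defs.values():
                mask = mask_by_kind[band.applicable_mask]
                for measure in ("ERSP_db", "ITC"):
                    value, n = band_summary(rois[roi][measure], mask, band)
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group,
                            "roi": roi,
                            "band": band.name,
                            "measure": measure,
                            "value": value,
                            "n_cells": n,
                        }
                    )
    return pd.DataFrame(rows)
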