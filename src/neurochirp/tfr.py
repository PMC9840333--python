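"""Complex Morlet wavelet decomposition, ERSP and inter-trial coherence.

Coefficients are obtained by FFT convolution of each trial with
unit-energy complex Morlet kernels.  Cells closer to an epoch edge than
half the kernel length are flagged invalid and excluded from every
summary (no padding is applied).

Conventions (recorded in the output metadata):

* frequency grid default 2-120 Hz in 1 Hz steps;
* cycles rule ``n_cycles(f) = max(3, f / 2)``;
* baseline window default -800 to -200 ms, divisive on trial-averaged
  power;
* dB as ``10 * log10`` of the power ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .preprocess import EpochSet

__all__ = [
    "TFDecomposition",
    "ERSPMap",
    "ITCMap",
    "default_freq_grid",
    "default_n_cycles",
    "morlet_kernel",
    "morlet_tf",
    "ersp",
    "itc",
]

#: Gaussian truncation of the wavelet, in standard deviations each side.
KERNEL_TRUNC_SD = 3.0


def default_freq_grid(fmin: float = 2.0, fmax: float = 120.0, step: float = 1.0) -> np.ndarray:
    return np.arange(fmin, fmax + step / 2, step)


def default_n_cycles(freqs_hz: np.ndarray) -> np.ndarray:
    """Expanding-cycles rule: 3 cycles at low frequencies, f/2 above 6 Hz."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return np.maximum(3.0, freqs_hz / 2.0)


def morlet_kernel(freq_hz: float, n_cycles: float, rate: float) -> np.ndarray:
    """Unit-energy complex Morlet kernel, truncated at +/-KERNEL_TRUNC_SD sigma."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(KERNEL_TRUNC_SD * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq_hz * t)
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    return kernel


@dataclass
class TFDecomposition:
    """Per-trial complex wavelet coefficients on a frequency x time grid."""

    coeffs: np.ndarray  # (n_trials, n_freqs, n_times), complex
    freqs_hz: np.ndarray
    times_s: np.ndarray
    rate: float
    cycles_rule: str
    valid_mask: np.ndarray  # (n_freqs, n_times), bool
    decim: int = 1

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2


@dataclass
class ERSPMap:
    """Baseline-normalised power change in dB, trial-averaged."""

    values_db: np.ndarray  # (n_freqs, n_times)
    freqs_hz: np.ndarray
    times_s: np.ndarray
    baseline_window_s: tuple[float, float]
    n_trials: int
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ITCMap:
    """Inter-trial coherence: modulus of the trial-mean unit phase vector."""

    values: np.ndarray  # (n_freqs, n_times), in [0, 1]
    freqs_hz: np.ndarray
    times_s: np.ndarray
    n_trials: int
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def morlet_tf(
    roi_epochs: EpochSet,
    freqs_hz: np.ndarray | None = None,
    n_cycles: np.ndarray | str = "default",
    decim: int = 1,
    channel: int = 0,
) -> TFDecomposition:
    """Morlet decomposition of one (virtual) channel of an epoch set.

    Parameters
    ----------
    roi_epochs : EpochSet
        Typically the single-channel output of ``roi_average``; use
        ``channel`` to select a channel otherwise.
    freqs_hz : array, optional
        Strictly increasing analysis frequencies; defaults to 2-120 Hz
        in 1 Hz steps.
    n_cycles : array or "default"
        Cycles per frequency; the default rule is ``max(3, f/2)``.
    decim : int
        Keep every ``decim``-th time sample of the output (the
        convolution itself runs at full rate).
    """
    if freqs_hz is None:
        freqs_hz = default_freq_grid()
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.ndim != 1 or np.any(np.diff(freqs_hz) <= 0):
        raise ValueError("freqs_hz must be strictly increasing")
    rate = roi_epochs.rate
    if freqs_hz.max() >= rate / 2:
        raise ValueError(
            f"max frequency {freqs_hz.max()} Hz is not below Nyquist {rate / 2} Hz"
        )
    if isinstance(n_cycles, str):
        if n_cycles != "default":
            raise ValueError("n_cycles must be an array or 'default'")
        cycles = default_n_cycles(freqs_hz)
        rule = "max(3, f/2)"
    else:
        cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs_hz.shape).copy()
        rule = "user-specified"

    x = roi_epochs.data[:, channel, :]
    n_trials, n_times = x.shape
    kernels = [morlet_kernel(f, c, rate) for f, c in zip(freqs_hz, cycles)]
    halves = np.array([(len(k) - 1) // 2 for k in kernels])
    if 2 * halves.max() + 1 > n_times:
        raise ValueError(
            f"epoch of {n_times} samples shorter than the longest wavelet "
            f"({2 * halves.max() + 1} samples at {freqs_hz[np.argmax(halves)]} Hz)"
        )

    nfft = next_fast_len(n_times + 2 * int(halves.max()))
    X = fft(x, nfft, axis=1)
    out_idx = np.arange(0, n_times, decim)
    coeffs = np.empty((n_trials, len(freqs_hz), len(out_idx)), dtype=complex)
    for j, (k, half) in enumerate(zip(kernels, halves)):
        K = fft(np.conj(k[::-1]), nfft)
        conv = ifft(X * K[None, :], axis=1)
        # 'same' alignment: coefficient at sample i uses kernel centred on i
        full = conv[:, half : half + n_times]
        coeffs[:, j, :] = full[:, out_idx]

    valid = np.zeros((len(freqs_hz), len(out_idx)), dtype=bool)
    for j, half in enumerate(halves):
        valid[j] = (out_idx >= half) & (out_idx <= n_times - 1 - half)

    times = roi_epochs.tmin_s + out_idx / rate
    return TFDecomposition(
        coeffs=coeffs,
        freqs_hz=freqs_hz,
        times_s=times,
        rate=rate,
        cycles_rule=rule,
        valid_mask=valid,
        decim=decim,
    )


def ersp(tf: TFDecomposition, baseline_window_s: tuple[float, float] = (-0.8, -0.2)) -> ERSPMap:
    """ERSP in dB: ``10*log10(mean power / mean baseline power per frequency)``.

    The baseline is the trial-averaged power within ``baseline_window_s``,
    restricted to valid (edge-free) cells.  Frequencies without any valid
    baseline cell yield NaN rows with a warning.
    """
    b0, b1 = baseline_window_s
    if b0 >= b1:
        raise ValueError("baseline window must be ordered")
    if b1 > 0:
        raise ValueError("baseline window must lie in the pre-stimulus period")
    in_window = (tf.times_s >= b0) & (tf.times_s < b1)
    if not in_window.any():
        raise ValueError("baseline window contains no time samples")

    mean_power = tf.power.mean(axis=0)  # (n_freqs, n_times)
    baseline = np.full(len(tf.freqs_hz), np.nan)
    for j in range(len(tf.freqs_hz)):
        cells = in_window & tf.valid_mask[j]
        if cells.any():
            baseline[j] = mean_power[j, cells].mean()
    no_base = np.isnan(baseline)
    if no_base.all():
        raise ValueError("no frequency has a valid baseline cell in the window")
    if no_base.any():
        warnings.warn(
            f"no valid baseline cells at {tf.freqs_hz[no_base]} Hz; rows set to NaN",
            stacklevel=2,
        )
    # roundoff from the FFT convolution makes exact zeros ~1e-18, so the
    # degeneracy check is relative to the map's overall power scale
    power_floor = 1e-12 * max(float(mean_power.max()), 1e-300)
    if np.any(baseline[~no_base] <= power_floor):
        raise ValueError("zero baseline power encountered (degenerate input)")

    with np.errstate(divide="ignore", invalid="ignore"):
        values = 10.0 * np.log10(mean_power / baseline[:, None])
    values[no_base, :] = np.nan
    return ERSPMap(
        values_db=values,
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        baseline_window_s=(b0, b1),
        n_trials=tf.n_trials,
        valid_mask=tf.valid_mask & ~no_base[:, None],
        meta={
            "cycles_rule": tf.cycles_rule,
            "baseline_statistic": "divisive, trial-averaged power",
            "db_convention": "10*log10(power ratio)",
        },
    )


def itc(tf: TFDecomposition) -> ITCMap:
    """Inter-trial coherence: ``| mean_trials coeff / |coeff| |`` per cell.

    Trials with an exactly-zero coefficient are excluded at that cell.
    Requires at least two trials.
    """
    if tf.n_trials < 2:
        raise ValueError("ITC undefined for fewer than 2 trials")
    mag = np.abs(tf.coeffs)
    nonzero = mag > 0
    unit = np.zeros_like(tf.coeffs)
    np.divide(tf.coeffs, mag, out=unit, where=nonzero)
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.abs(unit.sum(axis=0)) / counts
    values = np.where(counts > 0, values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return ITCMap(
        values=values,
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        n_trials=tf.n_trials,
        valid_mask=tf.valid_mask,
        meta={"cycles_rule": tf.cycles_rule},
    )
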