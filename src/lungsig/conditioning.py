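"""Band-split filtering and moving-variance envelope extraction.

The analysis splits each channel into a low and a high band — sound below
2 Hz / above 150 Hz, ECG below 150 Hz / above 150 Hz — and summarizes the
filtered signal by a sliding-window variance (250 ms window, i.e. 1000
samples at 4 kHz), which acts as an energy envelope.

Filters are 4th-order Butterworth applied forward-backward (zero phase) so
envelopes stay aligned with the cycle annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError

__all__ = ["FilterSpec", "EnvelopeSeries", "BAND_PRESETS", "apply_filter", "moving_variance"]


@dataclass(frozen=True)
class FilterSpec:
    """One band of the band-split: kind, cutoff(s) in Hz, and the channel it serves."""

    kind: str  # lowpass | highpass | bandpass
    cutoff_hz: tuple
    channel_role: str  # sound | ecg

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        cutoffs = tuple(float(c) for c in (
            self.cutoff_hz if isinstance(self.cutoff_hz, (tuple, list))
            else (self.cutoff_hz,)))
        object.__setattr__(self, "cutoff_hz", cutoffs)
        expected = 2 if self.kind == "bandpass" else 1
        if len(cutoffs) != expected:
            raise ConfigurationError(f"{self.kind} needs {expected} cutoff(s)")
        if any(c <= 0 for c in cutoffs):
            raise ConfigurationError("cutoffs must be positive")
        if self.kind == "bandpass" and not cutoffs[0] < cutoffs[1]:
            raise ConfigurationError("bandpass lower cutoff must be below upper")


#: Band presets of the analysis; names follow the channel/band they extract.
BAND_PRESETS = {
    "sound_low": FilterSpec("lowpass", (2.0,), "sound"),
    "sound_high": FilterSpec("highpass", (150.0,), "sound"),
    "ecg_low": FilterSpec("lowpass", (150.0,), "ecg"),
    "ecg_high": FilterSpec("highpass", (150.0,), "ecg"),
}


@dataclass
class EnvelopeSeries:
    """Moving-variance envelope aligned to the source time base.

    Element ``k`` is the population variance of the window starting at
    ``k * hop_samples``; the window center sits at
    ``(k * hop_samples + window_samples / 2) / sampling_rate_hz`` seconds.
    """

    values: np.ndarray
    window_samples: int
    hop_samples: int
    sampling_rate_hz: Optional[float] = None
    source_band: Optional[FilterSpec] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ConfigurationError("variance envelope values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


def apply_filter(x, spec: FilterSpec, sampling_rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band split; output has the input's length.

    Raises ConfigurationError for cutoffs at/above Nyquist or signals shorter
    than the filter warm-up (no silent padding).
    """
    x = np.asarray(x, dtype=float)
    nyquist = sampling_rate_hz / 2.0
    if any(c >= nyquist for c in spec.cutoff_hz):
        raise ConfigurationError(
            f"cutoff(s) {spec.cutoff_hz} must lie below Nyquist {nyquist} Hz")
    cut = spec.cutoff_hz if spec.kind == "bandpass" else spec.cutoff_hz[0]
    sos = sps.butter(order, cut, btype=spec.kind, fs=sampling_rate_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default
    if x.size <= padlen:
        raise ConfigurationError(
            f"signal of {x.size} samples is shorter than the filter warm-up ({padlen})")
    return sps.sosfiltfilt(sos, x)


def moving_variance(x, window_samples: int, hop_samples: int = 1,
                    sampling_rate_hz: Optional[float] = None,
                    source_band: Optional[FilterSpec] = None) -> EnvelopeSeries:
    """Population variance over a sliding window (the energy envelope).

    Output element ``k`` covers samples ``[k*hop, k*hop + window)``; the series
    has ``floor((len(x) - window) / hop) + 1`` elements. Computed via centered
    cumulative sums, O(n) regardless of window length.
    """
    x = np.asarray(x, dtype=float)
    if window_samples <= 1:
        raise ConfigurationError("window_samples must exceed 1")
    if hop_samples < 1:
        raise ConfigurationError("hop_samples must be a positive integer")
    if window_samples > x.size:
        raise ConfigurationError(
            f"window of {window_samples} exceeds signal length {x.size}")
    # global centering plus extended-precision cumulative sums keep the
    # E[x^2] - E[x]^2 cancellation far below the per-window variance even
    # for nearly constant windows
    y = (x - x.mean()).astype(np.longdouble)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    w = window_samples
    starts = np.arange(0, x.size - w + 1, hop_samples)
    mean = (c1[starts + w] - c1[starts]) / w
    var = ((c2[starts + w] - c2[starts]) / w - mean ** 2).astype(float)
    np.maximum(var, 0.0, out=var)
    return EnvelopeSeries(var, window_samples, hop_samples,
                          sampling_rate_hz=sampling_rate_hz, source_band=source_band)
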