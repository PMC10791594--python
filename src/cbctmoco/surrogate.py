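"""Respiratory surrogate signals extracted from the projections themselves.

The Intensity Analysis (IA) method sums the pixel intensities of each
projection and splits the resulting 1-D signal into a low-frequency component
(slow gantry-rotation dependence of the path lengths) and a high-frequency
component that tracks respiration.  A zero-phase Butterworth high-pass at
0.1 Hz separates the two: normal adult respiration sits at roughly
0.2-0.5 Hz while a full gantry rotation takes about a minute (~0.017 Hz).

The second signal of the two-signal correspondence model is the temporal
gradient of the IA signal (breathing-rate information, as in 5-D lung motion
models), lightly smoothed to curb noise amplification.  Both signals are
normalized to zero mean and unit sample standard deviation before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, detrend, filtfilt

from .geometry import ProjectionStack

DEFAULT_BAND_SPLIT_HZ = 0.1


@dataclass
class Trace:
    """A 1-D signal sampled at the projection timestamps."""

    values: np.ndarray
    sample_times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_times = np.asarray(self.sample_times, dtype=np.float64)
        if self.values.shape != self.sample_times.shape or self.values.ndim != 1:
            raise ValueError("values and sample_times must be equal-length 1-D arrays")
        if self.values.size >= 2 and np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")


def ia_extract(
    projs: ProjectionStack, band_split_hz: float = DEFAULT_BAND_SPLIT_HZ
) -> Trace:
    """High-frequency component of the per-projection intensity sums.

    Operates on the line-integral (log-converted) projections.  Requires at
    least 16 frames at an approximately uniform frame rate.
    """
    if projs.n_frames < 16:
        raise ValueError("IA extraction needs at least 16 frames")
    sums = projs.data.reshape(projs.n_frames, -1).sum(axis=1).astype(np.float64)
    if not np.all(np.isfinite(sums)):
        raise ValueError("non-finite projection sums")
    times = projs.geometry.times
    dt = np.diff(times)
    fs = 1.0 / float(np.mean(dt))
    if np.max(np.abs(dt - np.mean(dt))) > 0.25 * np.mean(dt):
        raise ValueError("frame rate is not approximately uniform")
    wn = band_split_hz / (0.5 * fs)
    if not 0 < wn < 1:
        raise ValueError("band_split_hz must lie below the Nyquist frequency")
    b, a = butter(2, wn, btype="highpass")
    # linear detrend first: filtfilt edge transients on a strong ramp leak
    # into the passband otherwise
    high = filtfilt(b, a, detrend(sums, type="linear"))
    return Trace(high, times, label="ia")


def temporal_gradient(trace: Trace, smooth_window: int = 3) -> Trace:
    """Central-difference temporal derivative, lightly smoothed.

    One-sided differences at the ends; a ``smooth_window``-sample moving
    average curbs noise amplification before normalization.
    """
    if trace.values.size < 3:
        raise ValueError("temporal gradient needs at least 3 samples")
    grad = np.gradient(trace.values, trace.sample_times)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(grad, pad, mode="edge")
        grad = np.convolve(padded, kernel, mode="valid")[: grad.size]
    return Trace(grad, trace.sample_times, label=f"d({trace.label})/dt")


def normalize_signal(trace: Trace) -> Trace:
    """Zero-mean, unit sample-standard-deviation (ddof=1) copy of the trace."""
    v = trace.values
    std = np.std(v, ddof=1)
    if std == 0:
        raise ValueError("cannot normalize a constant trace")
    return Trace((v - v.mean()) / std, trace.sample_times, label=trace.label)


@dataclass
class SurrogateMatrix:
    """N_t x N_s matrix of (normalized) surrogate values driving the model."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("surrogate values must be N_t x N_s")
        if not self.names:
            self.names = [f"s{i + 1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per signal required")
        if self.normalized:
            self._check_normalized()

    def _check_normalized(self) -> None:
        means = self.values.mean(axis=0)
        if np.max(np.abs(means)) >= 1e-8:
            raise ValueError("normalized surrogate columns must have zero mean")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_signals(self) -> int:
        return self.values.shape[1]

    def row(self, t: int) -> np.ndarray:
        return self.values[t]

    @classmethod
    def from_traces(cls, traces: list[Trace], normalize: bool = True) -> "SurrogateMatrix":
        if normalize:
            traces = [normalize_signal(tr) for tr in traces]
        values = np.stack([tr.values for tr in traces], axis=1)
        names = [tr.label or f"s{i + 1}" for i, tr in enumerate(traces)]
        return cls(values, names, normalized=normalize)


def ia_surrogates(
    projs: ProjectionStack, band_split_hz: float = DEFAULT_BAND_SPLIT_HZ
) -> SurrogateMatrix:
    """The IA signal and its temporal gradient, normalized, as a two-column matrix."""
    s1 = ia_extract(projs, band_split_hz)
    s2 = temporal_gradient(s1)
    return SurrogateMatrix.from_traces([s1, s2], normalize=True)
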