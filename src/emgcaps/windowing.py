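"""Sliding-window analysis of continuous multi-channel sEMG recordings.

A continuous recording (channels x samples) is cut into overlapping analysis
windows of length ``w`` advanced by an increment interval ``tau``; each window
is the unit of classification.  A window's per-channel signal is additionally
reshaped into an ``n x l`` segment matrix, where ``(n, l)`` is the factor pair
of ``w`` whose difference ``|n - l|`` is minimal — for the default ``w = 300``
this gives a 15 x 20 matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import isqrt
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "RecordingBuffer",
    "WindowingConfig",
    "SignalWindow",
    "SegmentPlan",
    "slide_windows",
    "solve_segmentation",
    "stack_segments",
    "bandpass_notch",
    "read_recording_text",
    "load_recording",
    "save_recording",
    "save_windows",
    "load_windows",
]


class ConfigurationError(ValueError):
    """Raised for invalid windowing or training configuration values."""


@dataclass
class RecordingBuffer:
    """A continuous multi-channel recording.

    Parameters
    ----------
    data : ndarray, shape (channels, samples)
        Raw signal, microvolt-scale arbitrary units.
    fs : float
        Sampling rate in Hz.
    label : optional
        Gesture identifier for the whole recording (one gesture per
        acquisition period).
    """

    data: np.ndarray
    fs: float = 1000.0
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording must have >= 1 channel and >= 1 sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowingConfig:
    """Window length ``w`` and increment interval ``tau``, in samples."""

    w: int = 300
    tau: int = 50

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ConfigurationError(f"window length w must be >= 1, got {self.w}")
        if not 1 <= self.tau <= self.w:
            raise ConfigurationError(
                f"increment tau must satisfy 1 <= tau <= w, got tau={self.tau}, w={self.w}"
            )


@dataclass
class SignalWindow:
    """One ``w``-sample, multi-channel slice of a recording."""

    data: np.ndarray  # (channels, w)
    fs: float = 1000.0
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be 2-D (channels x w)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def w(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SegmentPlan:
    """A factorization ``w = n * l`` minimizing ``|n - l|`` with ``n <= l``."""

    n: int
    l: int

    @property
    def dif(self) -> int:
        return abs(self.n - self.l)


def slide_windows(
    buffer: RecordingBuffer, config: WindowingConfig = WindowingConfig()
) -> list[SignalWindow]:
    """Cut a recording into overlapping windows.

    Window ``k`` covers the half-open sample range
    ``[k*tau, k*tau + w)``; trailing samples shorter than ``w`` are dropped.
    Returns ``floor((samples - w) / tau) + 1`` windows when the recording is
    at least one window long, else an empty list.  The buffer's label is
    propagated to every window.
    """
    w, tau = config.w, config.tau
    n_samples = buffer.n_samples
    if n_samples < w:
        return []
    count = (n_samples - w) // tau + 1
    return [
        SignalWindow(buffer.data[:, k * tau : k * tau + w].copy(), buffer.fs, buffer.label)
        for k in range(count)
    ]


def solve_segmentation(w: int) -> SegmentPlan:
    """Find the factor pair ``(n, l)`` of ``w`` minimizing ``|n - l|``.

    Subject to ``n * l = w``; the mirror tie between ``(n, l)`` and
    ``(l, n)`` is broken toward ``n <= l``, so ``w = 300`` yields
    ``(15, 20)``.
    """
    w = int(w)
    if w < 1:
        raise ValueError(f"window length must be a positive integer, got {w}")
    # The balanced pair is the largest divisor n <= sqrt(w); |n - l| shrinks
    # monotonically as n grows toward sqrt(w).
    for n in range(isqrt(w), 0, -1):
        if w % n == 0:
            return SegmentPlan(n=n, l=w // n)
    raise AssertionError("unreachable: 1 divides every positive integer")


def stack_segments(channel_signal: np.ndarray, plan: SegmentPlan) -> np.ndarray:
    """Stack a length-``w`` channel signal into an ``n x l`` segment matrix.

    Row ``i`` holds samples ``[i*l, (i+1)*l)`` in original order, so
    row-wise flattening recovers the input exactly.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size != plan.n * plan.l:
        raise ValueError(
            f"signal length {x.size} does not match plan {plan.n} x {plan.l}"
        )
    return x.reshape(plan.n, plan.l)


def bandpass_notch(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float] = (20.0, 500.0),
    notch: Optional[float] = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Optional 20-500 Hz band-pass plus 50 Hz notch (plumbing, not the method).

    Acquisition hardware normally applies these filters on-device; this helper
    exists for recordings that arrive unfiltered.  The band-pass upper edge is
    clipped below Nyquist.
    """
    from scipy import signal as sps

    x = np.atleast_2d(np.asarray(data, dtype=float))
    nyq = fs / 2.0
    hi = min(band[1], nyq * 0.999)
    sos = sps.butter(order, [band[0] / nyq, hi / nyq], btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    if notch is not None and notch < nyq:
        b, a = sps.iirnotch(notch, Q=30.0, fs=fs)
        y = sps.filtfilt(b, a, y, axis=-1)
    return y


# ---------------------------------------------------------------------------
# I/O: delimited text (one row per sample, one column per channel) and a
# binary array container (.npz) with fields data / fs / label.
# ---------------------------------------------------------------------------

def read_recording_text(
    path: Union[str, Path],
    fs: float = 1000.0,
    label: Optional[int] = None,
    delimiter: Optional[str] = None,
) -> RecordingBuffer:
    """Load a recording from delimited text (samples x channels on disk)."""
    arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return RecordingBuffer(arr.T, fs=fs, label=label)


def save_recording(path: Union[str, Path], buffer: RecordingBuffer) -> None:
    label = -1 if buffer.label is None else int(buffer.label)
    np.savez(path, data=buffer.data, fs=buffer.fs, label=label)


def load_recording(path: Union[str, Path]) -> RecordingBuffer:
    with np.load(path) as z:
        label = int(z["label"])
        return RecordingBuffer(
            z["data"], fs=float(z["fs"]), label=None if label < 0 else label
        )


def save_windows(path: Union[str, Path], windows: Sequence[SignalWindow]) -> None:
    """Write a window tensor (count x channels x w) plus labels and fs."""
    if not windows:
        raise ValueError("no windows to save")
    data = np.stack([win.data for win in windows])
    labels = np.array([-1 if w.label is None else int(w.label) for w in windows])
    np.savez(path, data=data, labels=labels, fs=windows[0].fs)


def load_windows(path: Union[str, Path]) -> list[SignalWindow]:
    with np.load(path) as z:
        fs = float(z["fs"])
        return [
            SignalWindow(d, fs=fs, label=None if lab < 0 else int(lab))
            for d, lab in zip(z["data"], z["labels"])
        ]
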