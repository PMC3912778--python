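"""Preprocessing of multichannel surface EHG.

The raw recording is a 5-channel monopolar matrix sampled at a few hundred
hertz.  Uterine electrical activity carries its energy roughly between 0.1
and 4 Hz, so the chain applied here is:

1. 5th-order Butterworth band-pass, 0.1-4 Hz, applied zero-phase;
2. downsampling to 20 Hz (the 4 Hz band limit leaves ample margin below the
   new 10 Hz Nyquist frequency);
3. bipolar derivation, which cancels common-mode interference between
   neighbouring electrodes of the cross-shaped abdominal montage::

       B1 = M1 - M5    B2 = M5 - M3    B3 = M4 - M5    B4 = M5 - M2

Only the four bipolar channels are analysed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

MONOPOLAR_IDS: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")
BIPOLAR_IDS: tuple[str, ...] = ("B1", "B2", "B3", "B4")

#: electrode pair behind each bipolar channel (minuend, subtrahend)
BIPOLAR_PAIRS: dict[str, tuple[str, str]] = {
    "B1": ("M1", "M5"),
    "B2": ("M5", "M3"),
    "B3": ("M4", "M5"),
    "B4": ("M5", "M2"),
}


@dataclass
class MonopolarRecording:
    """Raw or preprocessed monopolar EHG matrix, one column per electrode."""

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...] = MONOPOLAR_IDS
    annotations: Optional[object] = None  # GroundTruth, when simulated

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_ids):
            raise ValueError(
                f"samples must be (n, {len(self.channel_ids)}); got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, cid: str) -> np.ndarray:
        return self.samples[:, self.channel_ids.index(cid)]


@dataclass
class BipolarRecording:
    """Four bipolar channels B1..B4 at the working rate (20 Hz by default)."""

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...] = BIPOLAR_IDS
    annotations: Optional[object] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_ids):
            raise ValueError(
                f"samples must be (n, {len(self.channel_ids)}); got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, cid: str) -> np.ndarray:
        return self.samples[:, self.channel_ids.index(cid)]


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 0.1,
    high: float = 4.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis.

    The filter is applied forward-backward (``sosfiltfilt``) so that event
    timing is preserved for the segment boundaries estimated later; the
    effective magnitude response is the squared one-pass response.
    """
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high; got low={low}, high={high}")
    if high >= fs / 2:
        raise ValueError(f"high edge {high} Hz not below Nyquist {fs / 2} Hz")
    x = np.asarray(x, dtype=float)
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x, axis=0)


def downsample(x: np.ndarray, fs: float, target_fs: float = 20.0) -> np.ndarray:
    """Reduce the sampling rate of an already band-limited series.

    Integer ratios (e.g. 500 -> 20 Hz) are decimated by plain sample picking,
    valid because the preceding 4 Hz band-pass leaves no content near the new
    Nyquist frequency.  Non-integer ratios fall back to polyphase resampling.
    """
    if target_fs >= fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {fs}")
    x = np.asarray(x, dtype=float)
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        return x[::q].copy()
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return _sig.resample_poly(x, frac.numerator, frac.denominator, axis=0)


def derive_bipolar(rec: MonopolarRecording) -> BipolarRecording:
    """Samplewise bipolar derivation B1..B4 from the five monopolar channels."""
    if len(rec.channel_ids) != 5:
        raise ValueError(f"expected 5 monopolar channels, got {len(rec.channel_ids)}")
    cols = []
    for bid in BIPOLAR_IDS:
        a, b = BIPOLAR_PAIRS[bid]
        cols.append(rec.channel(a) - rec.channel(b))
    return BipolarRecording(
        samples=np.column_stack(cols), fs=rec.fs, annotations=rec.annotations
    )


def preprocess(
    rec: MonopolarRecording,
    low: float = 0.1,
    high: float = 4.0,
    order: int = 5,
    target_fs: float = 20.0,
) -> BipolarRecording:
    """Full chain: band-pass filter, downsample, bipolar derivation."""
    filt = bandpass_filter(rec.samples, rec.fs, low=low, high=high, order=order)
    down = downsample(filt, rec.fs, target_fs)
    mono = MonopolarRecording(
        samples=down, fs=target_fs, channel_ids=rec.channel_ids,
        annotations=rec.annotations,
    )
    return derive_bipolar(mono)
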