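"""TOCO-like envelope generation from bipolar EHG.

A TOCO-like signal is a slow envelope of the EHG that mimics the familiar
tocodynamometer trace.  Two estimators are provided, both computed on the
"uterine specific" 0.34-1 Hz component over 30 s windows stepped every
0.25 s:

* ``rms`` -- the root-mean-square of each window;
* ``ufm`` -- the unnormalized first statistical moment of the window's
  spectrum, sum(f * P[f]) over the analysis band, with bin powers P[f] from
  a Hamming-windowed periodogram.

Envelope values are timestamped at the window *center*, which keeps onset
and offset estimates symmetric.  The first and last 30 s of every envelope
sit on filter/window edge transients and should be treated as untrusted
(`TocoLikeEnvelope.trusted_mask`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _sig

from .preprocessing import bandpass_filter

UTERINE_BAND: tuple[float, float] = (0.34, 1.0)
EDGE_GUARD_S: float = 30.0


@dataclass
class TocoLikeEnvelope:
    """Low-rate envelope of one bipolar channel, one value per window step."""

    values: np.ndarray
    step_s: float = 0.25
    window_s: float = 30.0
    method: str = "rms"
    source_channel: Optional[str] = None
    t0_s: float = 15.0  # time of first window center

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Window-center timestamps, seconds from the start of the signal."""
        return self.t0_s + np.arange(self.values.size) * self.step_s

    def trusted_mask(self, guard_s: float = EDGE_GUARD_S) -> np.ndarray:
        """False where the window overlaps the first/last `guard_s` seconds."""
        t = self.times
        lo = self.t0_s - self.window_s / 2 + guard_s
        hi = t[-1] + self.window_s / 2 - guard_s if t.size else 0.0
        return (t - self.window_s / 2 >= lo - 1e-9) & (t + self.window_s / 2 <= hi + 1e-9)


def uterine_band_filter(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = UTERINE_BAND,
    order: int = 5,
) -> np.ndarray:
    """Restrict a bipolar signal to the uterine-specific band (0.34-1 Hz)."""
    if fs / 2 <= band[1]:
        raise ValueError(f"fs/2 must exceed {band[1]} Hz, got fs={fs}")
    return bandpass_filter(x, fs, low=band[0], high=band[1], order=order)


def _window_starts(n: int, window_n: int, step_n: int) -> np.ndarray:
    if n < window_n:
        raise ValueError(f"signal length {n} shorter than window {window_n}")
    n_win = (n - window_n) // step_n + 1
    return np.arange(n_win) * step_n


def tocolike_rms(
    x: np.ndarray,
    fs: float,
    window_s: float = 30.0,
    step_s: float = 0.25,
    source_channel: Optional[str] = None,
) -> TocoLikeEnvelope:
    """RMS of sliding windows of the band-filtered signal."""
    x = np.asarray(x, dtype=float)
    window_n = int(round(window_s * fs))
    step_n = max(1, int(round(step_s * fs)))
    starts = _window_starts(x.size, window_n, step_n)
    cs = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    vals = np.sqrt(np.maximum(cs[starts + window_n] - cs[starts], 0.0) / window_n)
    return TocoLikeEnvelope(
        values=vals, step_s=step_n / fs, window_s=window_n / fs, method="rms",
        source_channel=source_channel, t0_s=window_n / (2 * fs),
    )


def _hamming_periodogram_matrix(
    windows: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin powers of each row from a Hamming-tapered periodogram.

    Normalised as PSD density times bin width (``periodogram(...,
    scaling='density')`` times fs/N), so the sum over any band recovers the
    signal power in that band -- for a pure tone, the sum over its spectral
    lobe is the tone power regardless of the taper's noise bandwidth.
    """
    m = windows.shape[-1]
    w = _sig.get_window("hamming", m)
    scale = m * (w**2).sum()
    demeaned = windows - windows.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(demeaned * w, axis=-1)
    p = (spec.real**2 + spec.imag**2) / scale
    if m % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    f = np.fft.rfftfreq(m, 1.0 / fs)
    return f, p


def tocolike_ufm(
    x: np.ndarray,
    fs: float,
    window_s: float = 30.0,
    step_s: float = 0.25,
    band: tuple[float, float] = UTERINE_BAND,
    source_channel: Optional[str] = None,
) -> TocoLikeEnvelope:
    """Unnormalized first spectral moment, sum(f * P[f]) per window.

    P[f] are periodogram bin powers (Hamming taper), so a pure tone of
    power P at frequency f0 yields approximately f0 * P.  Because the input
    is pre-filtered to `band`, summing over the band or the full axis is
    near-equivalent; the band sum is used.
    """
    x = np.asarray(x, dtype=float)
    window_n = int(round(window_s * fs))
    step_n = max(1, int(round(step_s * fs)))
    starts = _window_starts(x.size, window_n, step_n)
    windows = np.lib.stride_tricks.sliding_window_view(x, window_n)[::step_n]
    f, p = _hamming_periodogram_matrix(windows, fs)
    mask = (f >= band[0]) & (f <= band[1])
    vals = (p[:, mask] * f[mask]).sum(axis=1)
    return TocoLikeEnvelope(
        values=np.maximum(vals, 0.0), step_s=step_n / fs, window_s=window_n / fs,
        method="ufm", source_channel=source_channel, t0_s=window_n / (2 * fs),
    )


def tocolike(
    x: np.ndarray,
    fs: float,
    method: str = "rms",
    window_s: float = 30.0,
    step_s: float = 0.25,
    band: tuple[float, float] = UTERINE_BAND,
    source_channel: Optional[str] = None,
    prefilter: bool = True,
    filter_order: int = 5,
) -> TocoLikeEnvelope:
    """Band-filter a bipolar channel and compute the requested envelope."""
    y = uterine_band_filter(x, fs, band, filter_order) if prefilter else x
    if method == "rms":
        return tocolike_rms(y, fs, window_s, step_s, source_channel)
    if method == "ufm":
        return tocolike_ufm(y, fs, window_s, step_s, band, source_channel)
    raise ValueError(f"unknown TOCO-like method {method!r}")
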