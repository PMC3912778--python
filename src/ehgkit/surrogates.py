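"""Time-reversibility statistics and IAAFT surrogate data.

Temporal asymmetry is a signature of nonlinearity: a stationary linear
Gaussian process is statistically time-reversible.  The statistic used is
the third moment of lagged differences,

    Tr = (1/(N - tau)) * sum_i (x_i - x_{i-tau})^3,

which is exactly negated by reversing the series.  Significance is assessed
against iterative amplitude-adjusted Fourier-transform (IAAFT) surrogates,
which preserve the amplitude distribution exactly (every surrogate is a
permutation of the original values) and the power spectrum to high
accuracy, i.e. the null hypothesis of a monotonically transformed linear
Gaussian process.  The z-score

    z = |Tr_orig - <Tr_surr>| / SD(Tr_surr)

is large when the observed asymmetry cannot be explained by that null.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

SeedLike = Union[int, np.random.Generator, None]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def time_reversibility(x: np.ndarray, tau: int = 1) -> float:
    """Third-order difference statistic of temporal asymmetry."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if tau < 1 or n <= tau:
        raise ValueError(f"need 0 < tau < len(x); got tau={tau}, len={n}")
    d = x[tau:] - x[:-tau]
    return float(np.sum(d**3) / (n - tau))


def iaaft_surrogate(
    x: np.ndarray,
    rng: SeedLike = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """One IAAFT surrogate of `x`.

    Alternates spectrum adjustment (impose the original Fourier amplitudes)
    with rank remapping onto the original sorted values, stopping after
    `max_iter` iterations or when the relative spectral error falls below
    `tol`.  The final step is the amplitude adjustment, so the returned
    series is exactly a permutation of `x`.
    """
    rng = _as_rng(rng)
    x = np.asarray(x, dtype=float)
    n = x.size
    sorted_vals = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    target_norm = np.linalg.norm(target_amp)
    s = rng.permutation(x)
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.maximum(mag, 1e-300), 1.0)
        s = np.fft.irfft(target_amp * phase, n)
        ranks = np.argsort(np.argsort(s))
        s = sorted_vals[ranks]
        err = np.linalg.norm(np.abs(np.fft.rfft(s)) - target_amp) / target_norm
        if err < tol:
            break
    return s


def surrogate_series(
    x: np.ndarray,
    n: int = 100,
    seed: SeedLike = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Stack of `n` independent IAAFT surrogates, shape (n, len(x))."""
    rng = _as_rng(seed)
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError(f"series too short for surrogate testing ({x.size} < 64)")
    return np.stack([iaaft_surrogate(x, rng, max_iter, tol) for _ in range(n)])


def tr_zscore(
    x: np.ndarray, surrogates: np.ndarray, tau: int = 1
) -> float:
    """Surrogate z-score of the time-reversibility statistic."""
    surrogates = np.atleast_2d(np.asarray(surrogates, dtype=float))
    if surrogates.shape[0] < 2:
        raise ValueError("need at least 2 surrogates")
    tr_org = time_reversibility(x, tau)
    tr_surr = np.array([time_reversibility(s, tau) for s in surrogates])
    sd = tr_surr.std()
    if sd == 0:
        if np.allclose(tr_surr, tr_org):
            return 0.0
        raise ValueError("zero surrogate spread; z-score undefined")
    return float(abs(tr_org - tr_surr.mean()) / sd)
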