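"""The eleven spectral, temporal and nonlinear features of a segment.

Motion artifacts change a window of EHG in characteristic ways: they push
spectral energy above 1 Hz, create abrupt large-amplitude excursions, and
break the time symmetry of the series.  The feature set quantifies this:

spectral
    E1, E2, E3 -- energy fractions in 0.1-0.3, 0.3-1 and 1-4 Hz, from a
    single Hamming-windowed periodogram of the whole segment, normalised by
    the 0.1-4 Hz total so E1 + E2 + E3 = 1.
temporal
    sigma_x (standard deviation); RA = (max - min) / sigma_x; kappa
    (kurtosis, fourth standardized moment, Gaussian -> 3); MD_bs and MD_x,
    the maximum one-sample derivative normalised by the baseline SD and the
    segment SD respectively; R_RMS, segment RMS over baseline RMS.
nonlinear
    En, sample entropy with template length m = 3, tolerance r = 0.15 x
    segment SD, Chebyshev distance, self-matches excluded; Tr_z, the
    IAAFT-surrogate z-score of the time-reversibility statistic.

Baseline-normalised features (MD_bs, R_RMS) refer to quiet stretches of the
same channel of the same recording, held in a `BaselineReference`.

Degenerate inputs (zero variance, zero spectral energy) raise
`FeatureError` naming the feature rather than returning sentinels; callers
exclude such segments from training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from .detection import BaselineTrack, SegmentCandidate
from .envelopes import TocoLikeEnvelope
from .surrogates import SeedLike, surrogate_series, time_reversibility, tr_zscore

FEATURE_NAMES: tuple[str, ...] = (
    "E1", "E2", "E3", "sigma_x", "RA", "kappa",
    "MD_bs", "MD_x", "R_RMS", "En", "Tr_z",
)

#: spectral band edges, Hz
BAND_E1 = (0.1, 0.3)
BAND_E2 = (0.3, 1.0)
BAND_E3 = (1.0, 4.0)


class FeatureError(ValueError):
    """A feature is undefined for this segment (e.g. 0/0)."""

    def __init__(self, feature: str, message: str):
        self.feature = feature
        super().__init__(f"{feature}: {message}")


@dataclass
class BaselineReference:
    """Quiet-signal statistics of one channel of one recording session."""

    samples: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("baseline reference is empty")
        self.sigma_bs = float(self.samples.std())
        self.rms_bs = float(np.sqrt(np.mean(self.samples**2)))
        if self.sigma_bs <= 0:
            raise FeatureError("sigma_bs", "baseline reference has zero variance")


@dataclass
class FeatureVector:
    """The 11 features of one segment plus provenance and label."""

    E1: float
    E2: float
    E3: float
    sigma_x: float
    RA: float
    kappa: float
    MD_bs: float
    MD_x: float
    R_RMS: float
    En: float
    Tr_z: float
    channel: str = ""
    onset_s: float = float("nan")
    offset_s: float = float("nan")
    label: Optional[str] = None

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d.update(channel=self.channel, onset_s=self.onset_s,
                 offset_s=self.offset_s, label=self.label)
        return d


def extract_baseline_reference(
    x: np.ndarray,
    fs: float,
    env: TocoLikeEnvelope,
    bl: Optional[BaselineTrack] = None,
    frac: float = 0.10,
    window_s: float = 240.0,
    min_duration_s: float = 30.0,
    channel: str = "",
) -> BaselineReference:
    """Collect quiet EHG stretches of one channel as the baseline reference.

    An envelope step qualifies when its value lies within the lowest `frac`
    of the centered `window_s` window around it -- the same values averaged
    by the baseline estimator.  The EHG samples under qualifying window
    centers are concatenated; at least `min_duration_s` seconds must
    qualify.
    """
    if bl is not None:
        window_s, frac = bl.window_s, bl.frac
    x = np.asarray(x, dtype=float)
    e = env.values
    n = e.size
    half = int(round(window_s / (2 * env.step_s)))
    if (n - 1) * env.step_s < window_s:
        raise ValueError("envelope shorter than the baseline window")
    qual = np.zeros(n, dtype=bool)
    for k in range(n):
        lo = max(0, k - half)
        hi = min(n, k + half + 1)
        win = e[lo:hi]
        m = max(1, int(np.floor(frac * win.size)))
        thresh = np.partition(win, m - 1)[m - 1]
        qual[k] = e[k] <= thresh
    step_n = max(1, int(round(env.step_s * fs)))
    mask = np.zeros(x.size, dtype=bool)
    centers = env.times
    for k in np.flatnonzero(qual):
        i0 = int(round((centers[k] - env.step_s / 2) * fs))
        mask[max(0, i0) : min(x.size, i0 + step_n)] = True
    samples = x[mask]
    if samples.size < min_duration_s * fs:
        raise ValueError(
            f"only {samples.size / fs:.1f} s of quiet signal; "
            f"need {min_duration_s:.0f} s for a baseline reference"
        )
    return BaselineReference(samples=samples, channel=channel)


def spectral_band_ratios(
    x: np.ndarray, fs: float = 20.0
) -> tuple[float, float, float]:
    """Normalised band energies (E1, E2, E3); they sum to one by construction."""
    x = np.asarray(x, dtype=float)
    f, p = _sig.periodogram(x, fs=fs, window="hamming", scaling="spectrum")
    m1 = (f >= BAND_E1[0]) & (f < BAND_E1[1])
    m2 = (f >= BAND_E2[0]) & (f < BAND_E2[1])
    m3 = (f >= BAND_E3[0]) & (f <= BAND_E3[1])
    e1, e2, e3 = p[m1].sum(), p[m2].sum(), p[m3].sum()
    total = e1 + e2 + e3
    if total <= 0:
        raise FeatureError("E1", "segment has no spectral energy in 0.1-4 Hz")
    return float(e1 / total), float(e2 / total), float(e3 / total)


def temporal_features(
    x: np.ndarray, ref: BaselineReference
) -> tuple[float, float, float, float, float, float]:
    """(sigma_x, RA, kappa, MD_bs, MD_x, R_RMS) of a segment."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise FeatureError("sigma_x", "segment shorter than 2 samples")
    sigma_x = float(x.std())
    if sigma_x == 0:
        raise FeatureError("sigma_x", "segment has zero variance")
    ra = float((x.max() - x.min()) / sigma_x)
    kappa = float(_stats.kurtosis(x, fisher=False, bias=True))
    md = float(np.max(np.abs(np.diff(x))))
    md_bs = md / ref.sigma_bs
    md_x = md / sigma_x
    r_rms = float(np.sqrt(np.mean(x**2)) / ref.rms_bs)
    return sigma_x, ra, kappa, md_bs, md_x, r_rms


def sample_entropy(x: np.ndarray, m: int = 3, r: float = 0.15) -> float:
    """Sample entropy SampEn(m, r) with tolerance r x SD(x).

    Counts pairs of length-m templates within Chebyshev distance r*SD
    (self-matches excluded) and the fraction that still match at length
    m + 1; En = -ln(A / B).  Returns ``inf`` when no length-(m+1) pair
    matches, the conventional reading of a perfectly unpredictable series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise FeatureError("En", f"need more than m+1={m + 1} samples, got {n}")
    sd = x.std()
    if sd == 0:
        raise FeatureError("En", "segment has zero variance")
    tol = r * sd
    n_t = n - m  # number of templates that can be extended to length m+1
    # incremental Chebyshev distances between all template pairs
    d = np.abs(x[:n_t, None] - x[None, :n_t])
    for k in range(1, m):
        d = np.maximum(d, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]))
    match_m = d <= tol
    d = np.maximum(d, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]))
    match_m1 = d <= tol
    iu = np.triu_indices(n_t, k=1)
    b = int(match_m[iu].sum())
    a = int(match_m1[iu].sum())
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def featurize(
    seg: SegmentCandidate,
    ref: BaselineReference,
    n_surrogates: int = 100,
    seed: SeedLike = None,
    fs: Optional[float] = None,
    m: int = 3,
    r: float = 0.15,
    tau: int = 1,
) -> FeatureVector:
    """Compute all 11 features of a segment; deterministic given `seed`."""
    x = np.asarray(seg.samples, dtype=float)
    if x.size == 0:
        raise FeatureError("sigma_x", "segment carries no samples")
    fs = fs if fs is not None else seg.fs
    e1, e2, e3 = spectral_band_ratios(x, fs)
    sigma_x, ra, kappa, md_bs, md_x, r_rms = temporal_features(x, ref)
    en = sample_entropy(x, m=m, r=r)
    surr = surrogate_series(x, n=n_surrogates, seed=seed)
    trz = tr_zscore(x, surr, tau=tau)
    return FeatureVector(
        E1=e1, E2=e2, E3=e3, sigma_x=sigma_x, RA=ra, kappa=kappa,
        MD_bs=md_bs, MD_x=md_x, R_RMS=r_rms, En=en, Tr_z=trz,
        channel=seg.channel, onset_s=seg.onset_s, offset_s=seg.offset_s,
        label=seg.label,
    )
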