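"""Seeded generator of annotated, EHG-like multichannel recordings.

No public labor-EHG database with expert artifact labels exists, so every
downstream stage of this package is exercised on simulated recordings with
exact ground truth.  The simulator emulates the ingredients that matter for
segmentation and artifact classification:

* a 1/f-shaped Gaussian baseline, band-limited below 4 Hz, i.e. the
  bandwidth the preprocessing chain passes;
* contraction bursts: band-limited (0.34-1 Hz by default) Gaussian activity
  with a smooth Hann envelope, lasting tens of seconds, partially correlated
  across electrodes so that bipolar derivation does not cancel it;
* motion artifacts of three families -- impulsive spikes with an
  exponential electrode-recovery tail, baseline steps with a sharp edge and
  a slow sag, and broadband 1-4 Hz noise bursts;
* optional ECG-like (sharp >1 Hz quasi-periodic pulses of near-constant
  amplitude) and respiration-like (0.20-0.34 Hz, slowly varying)
  interference.

All randomness flows from one ``numpy.random.Generator`` seeded by the
config, so a fixed seed reproduces the recording bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .preprocessing import MONOPOLAR_IDS, MonopolarRecording

ARTIFACT_SUBTYPES = ("pulse", "step", "hf_burst")
INTERFERENCE_KINDS = ("ecg_like", "respiration_like")


class ConfigError(ValueError):
    """Invalid synthesis configuration; message names the offending field."""


@dataclass(frozen=True)
class Event:
    """One annotated ground-truth event."""

    kind: str                      # "contraction" | "artifact"
    channels: tuple[str, ...]      # affected monopolar electrodes
    onset_s: float
    offset_s: float
    subtype: str = ""              # artifact family, "" for contractions


@dataclass
class GroundTruth:
    """Exact event annotations of a simulated recording."""

    events: list[Event]
    duration_s: float

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0.0 <= ev.onset_s < ev.offset_s <= self.duration_s + 1e-9):
                raise ValueError(f"event outside recording span: {ev}")
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    def contractions(self) -> list[Event]:
        return [e for e in self.events if e.kind == "contraction"]

    def artifacts(self) -> list[Event]:
        return [e for e in self.events if e.kind == "artifact"]


@dataclass
class SynthesisConfig:
    """Study conditions for one simulated recording.

    ``snr_db`` is the ratio, in dB, between the mean contraction-burst power
    and the baseline-noise power, both measured inside ``contraction_band``
    on a monopolar channel.  Artifact amplitudes are expressed as multiples
    of the baseline-noise standard deviation; motion artifacts on abdominal
    surface recordings are typically an order of magnitude above the quiet
    baseline, which the defaults reflect.
    """

    duration_s: float
    fs_raw: float = 500.0
    n_channels: int = 5
    contraction_rate: float = 12.0            # events / hour
    contraction_duration_range: tuple[float, float] = (40.0, 90.0)
    contraction_band: tuple[float, float] = (0.34, 1.0)
    artifact_rate: float = 8.0                # events / hour
    artifact_types: tuple[str, ...] = ARTIFACT_SUBTYPES
    interference_flags: frozenset = frozenset()
    snr_db: float = 14.0
    rng_seed: int = 0
    # amplitude model (free parameters; not calibrated to any clinical cohort)
    noise_sigma: float = 5.0                  # baseline SD, arbitrary units
    pulse_amp_factor: float = 60.0
    step_amp_factor: float = 45.0
    burst_amp_factor: float = 30.0
    artifact_duration_range: tuple[float, float] = (20.0, 45.0)
    # baseline steps are brief repositioning episodes; both edges must fall
    # within one envelope window span for the shift to read as one event
    step_duration_range: tuple[float, float] = (15.0, 30.0)
    min_event_gap_s: float = 40.0
    shared_frac: float = 0.5                  # cross-channel contraction correlation
    gain_range: tuple[float, float] = (0.75, 1.25)

    def __post_init__(self) -> None:
        self.interference_flags = frozenset(self.interference_flags)
        self.artifact_types = tuple(self.artifact_types)
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if self.n_channels != len(MONOPOLAR_IDS):
            raise ConfigError(f"n_channels must be 5, got {self.n_channels}")
        lo, hi = self.contraction_band
        if not (0.0 < lo < hi < self.fs_raw / 2):
            raise ConfigError(
                f"contraction_band must lie within (0, fs_raw/2), got {self.contraction_band}"
            )
        if self.fs_raw <= 2 * max(hi, 4.0):
            raise ConfigError(
                f"fs_raw must exceed twice the highest synthesized frequency, got {self.fs_raw}"
            )
        if self.contraction_rate < 0:
            raise ConfigError(f"contraction_rate must be >= 0, got {self.contraction_rate}")
        if self.artifact_rate < 0:
            raise ConfigError(f"artifact_rate must be >= 0, got {self.artifact_rate}")
        for t in self.artifact_types:
            if t not in ARTIFACT_SUBTYPES:
                raise ConfigError(f"artifact_types contains unknown subtype {t!r}")
        for f in self.interference_flags:
            if f not in INTERFERENCE_KINDS:
                raise ConfigError(f"interference_flags contains unknown kind {f!r}")
        d0, d1 = self.contraction_duration_range
        if not (0 < d0 <= d1):
            raise ConfigError(
                f"contraction_duration_range must be increasing and positive, got {self.contraction_duration_range}"
            )
        if self.noise_sigma <= 0:
            raise ConfigError(f"noise_sigma must be > 0, got {self.noise_sigma}")
        if not (0.0 <= self.shared_frac <= 1.0):
            raise ConfigError(f"shared_frac must be in [0, 1], got {self.shared_frac}")


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    f_lo: float,
    f_hi: float,
    edge_frac: float = 0.1,
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [f_lo, f_hi] Hz.

    Spectral shaping is done in the Fourier domain with raised-cosine
    transitions placed *inside* the band, so essentially all energy stays
    within the requested range.
    """
    if n < 8:
        raise ValueError("band_noise needs n >= 8")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    width = edge_frac * (f_hi - f_lo)
    gain = np.zeros_like(f)
    core = (f >= f_lo + width) & (f <= f_hi - width)
    gain[core] = 1.0
    rise = (f >= f_lo) & (f < f_lo + width)
    gain[rise] = 0.5 * (1 - np.cos(np.pi * (f[rise] - f_lo) / width))
    fall = (f > f_hi - width) & (f <= f_hi)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - (f_hi - width)) / width))
    out = np.fft.irfft(spec * gain, n)
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate band noise (empty band?)")
    return out / sd


def pink_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    cutoff: float = 4.0,
    knee: float = 0.05,
) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise, low-pass limited at `cutoff`.

    Amplitude falls as 1/sqrt(f) above `knee` and rolls off steeply above
    `cutoff`, mimicking the smooth broadband background of preprocessed EHG.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, knee))
    shape /= np.sqrt(1.0 + (f / cutoff) ** 16)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n)
    return out / out.std()


def contraction_waveform(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float] = (0.34, 1.0),
    n_channels: int = 1,
    shared_frac: float = 0.5,
) -> np.ndarray:
    """Hann-tapered burst of band-limited activity, (n, n_channels).

    Channels mix one shared carrier with per-channel independent carriers so
    that electrode pairs stay only partially correlated -- as in real
    myometrial activity -- and the burst survives bipolar derivation.  The
    Hann envelope is normalised to unit mean square over the burst, so the
    waveform has unit average power per channel.
    """
    env = np.hanning(n)
    env = env / np.sqrt(np.mean(env**2))
    common = band_noise(rng, n, fs, *band)
    cols = []
    for _ in range(n_channels):
        own = band_noise(rng, n, fs, *band)
        u = np.sqrt(shared_frac) * common + np.sqrt(1.0 - shared_frac) * own
        cols.append(env * u)
    return np.column_stack(cols)


def inject_artifact(
    signal: np.ndarray,
    fs: float,
    subtype: str,
    onset_s: float,
    params: Optional[dict] = None,
) -> np.ndarray:
    """Return a copy of `signal` with one artifact waveform added.

    Subtypes
    --------
    pulse
        One or more (``n_pulses``) near-instantaneous deflections of
        amplitude ``amplitude`` spread over ``duration_s``, each followed by
        an exponential recovery tail (``tau_s``, ``tail_frac``) modelling
        electrode-interface charge redistribution.  The tail makes the
        waveform time-asymmetric, as real movement spikes are.
    step
        Sustained DC shift of ``height`` starting at the sharp onset edge.
        With ``duration_s`` the shift returns to zero at the offset edge;
        ``sag_frac`` > 0 lets the plateau relax exponentially after the
        jump.
    hf_burst
        Band-limited (``band``, default 1-4 Hz) Gaussian burst of standard
        deviation ``amplitude`` lasting ``duration_s``, Tukey-tapered.
        Needs randomness: supply ``rng`` or ``seed`` in `params`.
    """
    params = dict(params or {})
    x = np.asarray(signal, dtype=float).copy()
    n = x.shape[0]
    i0 = int(round(onset_s * fs))
    if not (0 <= i0 < n):
        raise ValueError(f"onset_s {onset_s} outside signal span")

    if subtype == "pulse":
        amp = float(params.get("amplitude", 1.0))
        n_pulses = int(params.get("n_pulses", 1))
        duration_s = float(params.get("duration_s", 0.0))
        tau_s = float(params.get("tau_s", 0.3))
        tail_frac = float(params.get("tail_frac", 0.4))
        signs = params.get("signs")
        if n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if signs is None:
            signs = [1.0 if k % 2 == 0 else -1.0 for k in range(n_pulses)]
        if n_pulses == 1:
            offsets = [0.0]
        else:
            offsets = list(np.linspace(0.0, duration_s, n_pulses))
        tail_n = max(1, int(round(5 * tau_s * fs)))
        tail = tail_frac * np.exp(-np.arange(1, tail_n + 1) / (tau_s * fs))
        for off, sgn in zip(offsets, signs):
            j = i0 + int(round(off * fs))
            if j >= n:
                continue
            x[j] += sgn * amp
            j1 = min(n, j + 1 + tail_n)
            x[j + 1 : j1] += sgn * amp * tail[: j1 - j - 1]
        return x

    if subtype == "step":
        h = float(params.get("height", 1.0))
        duration_s = params.get("duration_s")
        sag_frac = float(params.get("sag_frac", 0.0))
        tau_s = float(params.get("tau_s", 8.0))
        i1 = n if duration_s is None else min(n, i0 + int(round(duration_s * fs)))
        t = np.arange(i1 - i0) / fs
        plateau = h * ((1.0 - sag_frac) + sag_frac * np.exp(-t / tau_s))
        x[i0:i1] += plateau
        return x

    if subtype == "hf_burst":
        amp = float(params.get("amplitude", 1.0))
        duration_s = float(params.get("duration_s", 10.0))
        band = tuple(params.get("band", (1.0, 4.0)))
        low_band = tuple(params.get("low_band", (0.34, 1.0)))
        low_frac = float(params.get("low_frac", 0.15))
        rng = params.get("rng")
        if rng is None:
            rng = np.random.default_rng(params.get("seed", 0))
        m = int(round(duration_s * fs))
        if m < 8:
            raise ValueError("hf_burst duration too short")
        i1 = min(n, i0 + m)
        # broadband movement bursts concentrate in `band` but carry a
        # low-frequency skirt (`low_frac` of the power below 1 Hz)
        burst = np.sqrt(1.0 - low_frac) * band_noise(rng, m, fs, *band)
        if low_frac > 0:
            burst = burst + np.sqrt(low_frac) * band_noise(rng, m, fs, *low_band)
        taper = _sig.windows.tukey(m, alpha=0.25)
        x[i0:i1] += amp * (burst * taper)[: i1 - i0]
        return x

    raise ValueError(f"unknown artifact subtype {subtype!r}")


# ---------------------------------------------------------------------------
# event scheduling and full-recording synthesis
# ---------------------------------------------------------------------------

def _schedule_events(
    rng: np.random.Generator,
    duration_s: float,
    kinds: Sequence[str],
    dur_ranges: dict[str, tuple[float, float]],
    min_gap_s: float,
    edge_pad_s: float = 60.0,
    max_tries: int = 2000,
) -> list[tuple[str, float, float]]:
    """Place events of the requested kinds with a minimum mutual gap."""
    placed: list[tuple[str, float, float]] = []
    for kind in kinds:
        d0, d1 = dur_ranges[kind]
        for _ in range(max_tries):
            dur = rng.uniform(d0, d1)
            latest = duration_s - edge_pad_s - dur
            if latest <= edge_pad_s:
                break
            onset = rng.uniform(edge_pad_s, latest)
            ok = all(
                onset - (o + d) >= min_gap_s or o - (onset + dur) >= min_gap_s
                for _, o, d in placed
            )
            if ok:
                placed.append((kind, onset, dur))
                break
    return sorted(placed, key=lambda e: e[1])


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Average power of `x` inside `band`, via Fourier masking."""
    spec = np.fft.rfft(x, axis=0)
    f = np.fft.rfftfreq(x.shape[0], 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    spec = spec * mask[(...,) + (None,) * (x.ndim - 1)]
    filtered = np.fft.irfft(spec, x.shape[0], axis=0)
    return float(np.mean(filtered**2))


def _add_interference(
    rng: np.random.Generator, samples: np.ndarray, fs: float, sigma: float,
    flags: frozenset,
) -> None:
    n, nch = samples.shape
    t = np.arange(n) / fs
    if "respiration_like" in flags:
        # slowly wandering tone inside the respiratory 0.20-0.34 Hz band
        f_inst = 0.27 + 0.05 * band_noise(rng, n, fs, 0.003, 0.02) * 0.3
        f_inst = np.clip(f_inst, 0.20, 0.34)
        phase = 2 * np.pi * np.cumsum(f_inst) / fs
        amp = sigma * (1.0 + 0.25 * band_noise(rng, n, fs, 0.003, 0.02) * 0.3)
        wave = amp * np.sin(phase)
        for c in range(nch):
            samples[:, c] += rng.uniform(0.75, 1.25) * wave
    if "ecg_like" in flags:
        # quasi-constant spike train above 1 Hz (maternal heart ~72 bpm)
        period = 1.0 / 1.2
        width = 0.035
        beats = np.arange(1.0, n / fs - 1.0, period)
        beats = beats + rng.normal(0.0, 0.01, size=beats.size)
        wave = np.zeros(n)
        for b in beats:
            mask = np.abs(t - b) < 5 * width
            dt = t[mask] - b
            wave[mask] += -dt / width * np.exp(0.5 - 0.5 * (dt / width) ** 2)
        wave *= 1.5 * sigma
        for c in range(nch):
            samples[:, c] += rng.uniform(0.6, 1.4) * wave


def synthesize_recording(cfg: SynthesisConfig) -> tuple[MonopolarRecording, GroundTruth]:
    """Generate one annotated 5-channel monopolar recording.

    Returns the raw (unfiltered) monopolar matrix at ``cfg.fs_raw`` together
    with the exact event list.  Identical config (including seed) gives
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    fs = cfg.fs_raw
    n = int(round(cfg.duration_s * fs))
    nch = cfg.n_channels

    samples = np.column_stack(
        [cfg.noise_sigma * pink_noise(rng, n, fs) for _ in range(nch)]
    )
    noise_band_power = np.mean(
        [_band_power(samples[:, c], fs, cfg.contraction_band) for c in range(nch)]
    )

    hours = cfg.duration_s / 3600.0
    n_con = int(round(cfg.contraction_rate * hours))
    n_art = int(round(cfg.artifact_rate * hours))
    subtypes = [
        cfg.artifact_types[rng.integers(len(cfg.artifact_types))]
        for _ in range(n_art)
    ]
    kinds = ["contraction"] * n_con + subtypes
    rng.shuffle(kinds)
    dur_ranges = {
        "contraction": cfg.contraction_duration_range,
        "pulse": cfg.artifact_duration_range,
        "hf_burst": cfg.artifact_duration_range,
        "step": cfg.step_duration_range,
    }
    schedule = _schedule_events(
        rng, cfg.duration_s, kinds, dur_ranges, cfg.min_event_gap_s,
    )

    events: list[Event] = []
    target_power = noise_band_power * 10.0 ** (cfg.snr_db / 10.0)
    for kind, onset, dur in schedule:
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + int(round(dur * fs)))
        m = i1 - i0
        if kind == "contraction":
            burst = contraction_waveform(
                rng, m, fs, cfg.contraction_band, nch, cfg.shared_frac
            )
            gains = rng.uniform(*cfg.gain_range, size=nch)
            samples[i0:i1] += np.sqrt(target_power) * burst * gains
            events.append(Event("contraction", MONOPOLAR_IDS, onset, onset + dur))
        else:
            subtype = kind
            if subtype == "hf_burst":
                chans = tuple(
                    sorted(rng.choice(nch, size=rng.integers(2, 4), replace=False))
                )
            else:
                chans = tuple(
                    sorted(rng.choice(nch, size=rng.integers(1, 3), replace=False))
                )
            for c in chans:
                samples[:, c] = _inject_event_artifact(
                    samples[:, c], fs, subtype, onset, dur, cfg, rng
                )
            events.append(
                Event(
                    "artifact",
                    tuple(MONOPOLAR_IDS[c] for c in chans),
                    onset,
                    onset + dur,
                    subtype,
                )
            )

    _add_interference(rng, samples, fs, cfg.noise_sigma, cfg.interference_flags)

    rec = MonopolarRecording(samples=samples, fs=fs)
    gt = GroundTruth(events=events, duration_s=cfg.duration_s)
    rec.annotations = gt
    return rec, gt


def _inject_event_artifact(
    x: np.ndarray,
    fs: float,
    subtype: str,
    onset: float,
    dur: float,
    cfg: SynthesisConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realize one scheduled artifact event on a single channel."""
    sigma = cfg.noise_sigma
    if subtype == "pulse":
        n_pulses = max(3, int(rng.poisson(dur / 6.0)))
        signs = rng.choice([-1.0, 1.0], size=n_pulses)
        amp = cfg.pulse_amp_factor * sigma * rng.uniform(0.7, 1.3)
        return inject_artifact(
            x, fs, "pulse", onset,
            {"amplitude": amp, "n_pulses": n_pulses, "duration_s": dur,
             "signs": signs, "tau_s": 0.3, "tail_frac": 0.4},
        )
    if subtype == "step":
        h = cfg.step_amp_factor * sigma * rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0])
        return inject_artifact(
            x, fs, "step", onset,
            {"height": h, "duration_s": dur, "sag_frac": 0.3, "tau_s": dur / 4.0},
        )
    if subtype == "hf_burst":
        amp = cfg.burst_amp_factor * sigma * rng.uniform(0.7, 1.3)
        return inject_artifact(
            x, fs, "hf_burst", onset,
            {"amplitude": amp, "duration_s": dur, "band": (1.0, 4.0), "rng": rng},
        )
    raise ValueError(f"unknown artifact subtype {subtype!r}")
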