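"""Baseline tracking and candidate-segment detection on TOCO-like envelopes.

The baseline of each envelope is the average of the lowest 10% of values in
a centered 4-minute moving window.  Detection proceeds in two passes:

1. candidate windows are maximal runs where the envelope exceeds twice the
   baseline;
2. within each candidate window, only the part where the envelope also
   exceeds the baseline by more than 25% of that window's own peak
   excursion above baseline is kept,

and surviving runs must be sustained for at least 30 s.  Both criteria are
relative, so detection is invariant to any positive rescaling of the
envelope, and because the 25% rule refers to each candidate window's own
amplitude, a very large artifact does not mask a moderate contraction
nearby.  The rule admits other readings; this one is isolated in
`detect_segments` so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .envelopes import TocoLikeEnvelope
from .preprocessing import BIPOLAR_PAIRS
from .synthesis import Event, GroundTruth

LABEL_ARTIFACT = "artifacted"
LABEL_CLEAN = "nonartifacted"
LABEL_UNKNOWN = "unknown"


@dataclass
class BaselineTrack:
    """Baseline activity aligned sample-for-sample with its envelope."""

    values: np.ndarray
    step_s: float = 0.25
    window_s: float = 240.0
    frac: float = 0.10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("baseline values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SegmentCandidate:
    """A detected envelope excursion awaiting artifact classification."""

    channel: str
    method: str
    onset_s: float
    offset_s: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    fs: float = 20.0
    label: str = LABEL_UNKNOWN
    matched_event: Optional[Event] = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _lowest_frac_mean(win: np.ndarray, frac: float) -> float:
    m = max(1, int(np.floor(frac * win.size)))
    return float(np.mean(np.partition(win, m - 1)[:m]))


def estimate_baseline(
    env: TocoLikeEnvelope, window_s: float = 240.0, frac: float = 0.10
) -> BaselineTrack:
    """Mean of the lowest `frac` of envelope values per centered moving window.

    Windows are truncated at the envelope edges rather than padded.
    """
    n = len(env)
    if (n - 1) * env.step_s < window_s:
        raise ValueError(
            f"envelope spans {(n - 1) * env.step_s:.1f} s, shorter than the "
            f"{window_s:.0f} s baseline window"
        )
    half = int(round(window_s / (2 * env.step_s)))
    vals = np.empty(n)
    for k in range(n):
        lo = max(0, k - half)
        hi = min(n, k + half + 1)
        vals[k] = _lowest_frac_mean(env.values[lo:hi], frac)
    return BaselineTrack(values=vals, step_s=env.step_s, window_s=window_s, frac=frac)


def local_envelope_max(env: TocoLikeEnvelope, window_s: float = 240.0) -> np.ndarray:
    """Max of the envelope over the centered `window_s` window at each step."""
    size = 2 * int(round(window_s / (2 * env.step_s))) + 1
    # nearest-edge padding replicates the boundary value, which is already in
    # the truncated window, so this equals the truncated-window maximum
    return maximum_filter1d(env.values, size=size, mode="nearest")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as inclusive (start, stop) pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(a), int(b - 1)) for a, b in zip(edges[::2], edges[1::2])]


def detect_segments(
    env: TocoLikeEnvelope,
    bl: BaselineTrack,
    amp_factor: float = 2.0,
    rel_frac: float = 0.25,
    min_dur_s: float = 30.0,
    signal: Optional[np.ndarray] = None,
    fs: Optional[float] = None,
    channel: str = "",
) -> list[SegmentCandidate]:
    """Candidate segments where the envelope stays well above baseline.

    If `signal` (the 20 Hz preprocessed bipolar channel the envelope came
    from) is given, each candidate carries the matching sample slice.
    """
    if len(bl) != len(env) or abs(bl.step_s - env.step_s) > 1e-9:
        raise ValueError("envelope and baseline are on different grids")
    e = env.values
    b = bl.values
    coarse = e > amp_factor * b
    mask = np.zeros_like(coarse)
    for k0, k1 in _runs(coarse):
        peak = e[k0 : k1 + 1].max()
        thresh = b[k0 : k1 + 1] + rel_frac * (peak - b[k0 : k1 + 1])
        mask[k0 : k1 + 1] = e[k0 : k1 + 1] > thresh
    t = env.times
    segments: list[SegmentCandidate] = []
    if not mask.any():
        return segments
    for k0, k1 in _runs(mask):
        onset, offset = float(t[k0]), float(t[k1])
        if offset - onset < min_dur_s - 1e-9:
            continue
        seg = SegmentCandidate(
            channel=channel or (env.source_channel or ""),
            method=env.method,
            onset_s=onset,
            offset_s=offset,
        )
        if signal is not None and fs is not None:
            i0 = int(round(onset * fs))
            i1 = int(round(offset * fs))
            seg.samples = np.asarray(signal, dtype=float)[i0:i1].copy()
            seg.fs = fs
        segments.append(seg)
    return segments


def temporal_iou(a0: float, a1: float, b0: float, b1: float) -> float:
    """Intersection-over-union of two time intervals."""
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    return inter / union if union > 0 else 0.0


@dataclass
class DetectionCounts:
    """Event-level bookkeeping of detector output against ground truth."""

    hits: int = 0
    misses: int = 0
    false_alarms: int = 0

    @property
    def sensitivity(self) -> float:
        total = self.hits + self.misses
        return self.hits / total if total else float("nan")


def _event_touches_channel(ev: Event, bipolar_channel: str) -> bool:
    pair = BIPOLAR_PAIRS.get(bipolar_channel)
    if pair is None or not ev.channels:
        return True
    return bool(set(ev.channels) & set(pair))


def match_segments_to_truth(
    segs: Sequence[SegmentCandidate],
    gt: GroundTruth,
    iou_min: float = 0.3,
) -> tuple[list[SegmentCandidate], DetectionCounts]:
    """Label detected segments against simulator ground truth.

    A segment is labeled by the event it overlaps most (temporal IoU >=
    `iou_min`, restricted to events touching the segment's electrode pair).
    Any qualifying artifact event wins over contractions: a window holding
    both a contraction and an artifact is an artifacted window.  Artifact
    events mostly contained inside a longer segment also count, since an
    artifact anywhere in a window contaminates its features.  Segments with
    no qualifying event are `unknown` and counted as false alarms; events
    matched by no segment on any channel are misses.
    """
    counts = DetectionCounts()
    matched_events: set[int] = set()
    for seg in segs:
        best: Optional[Event] = None
        best_iou = 0.0
        artifact_hit: Optional[Event] = None
        for idx, ev in enumerate(gt.events):
            if not _event_touches_channel(ev, seg.channel):
                continue
            iou = temporal_iou(seg.onset_s, seg.offset_s, ev.onset_s, ev.offset_s)
            inter = max(0.0, min(seg.offset_s, ev.offset_s) - max(seg.onset_s, ev.onset_s))
            contained = inter >= 0.5 * (ev.offset_s - ev.onset_s)
            qualifies = iou >= iou_min or (ev.kind == "artifact" and contained)
            if not qualifies:
                continue
            matched_events.add(idx)
            if ev.kind == "artifact":
                if artifact_hit is None or iou > best_iou:
                    artifact_hit = ev
            if iou > best_iou:
                best_iou = iou
                best = ev
        if best is None:
            seg.label = LABEL_UNKNOWN
            counts.false_alarms += 1
        elif artifact_hit is not None:
            seg.label = LABEL_ARTIFACT
            seg.matched_event = artifact_hit
        else:
            seg.label = LABEL_CLEAN
            seg.matched_event = best
    counts.hits = len(matched_events)
    counts.misses = len(gt.events) - len(matched_events)
    return list(segs), counts
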