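"""End-to-end orchestration: simulate -> preprocess -> envelope -> detect ->
featurize -> classify, plus direct generation of labeled feature tables.

`run_pipeline` drives the whole chain from a single `PipelineConfig` whose
defaults are the standard operating point of the method (0.1-4 Hz 5th-order
band-pass, 20 Hz working rate, 0.34-1 Hz envelope band, 30 s / 0.25 s
envelope windows, 4-min / lowest-10% baseline, 2x / 25% / 30 s detection,
SampEn m=3 r=0.15, 100 surrogates, 2-fold CV x 50).  Every output file
carries the config hash and the seed, and a rerun with the same config
reproduces all numeric outputs byte-for-byte.

`simulate_labeled_windows` / `simulate_feature_table` generate balanced sets
of contraction and artifact windows directly -- the compact route to a
labeled training table when whole-recording simulation would be overkill.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ehgio
from .classify import (
    CLASSIFIER_KINDS,
    CVReport,
    repeated_two_fold_cv,
    sequential_forward_selection,
)
from .detection import (
    LABEL_ARTIFACT,
    LABEL_CLEAN,
    DetectionCounts,
    SegmentCandidate,
    detect_segments,
    estimate_baseline,
    match_segments_to_truth,
)
from .envelopes import TocoLikeEnvelope, tocolike, uterine_band_filter
from .features import (
    FEATURE_NAMES,
    BaselineReference,
    FeatureError,
    extract_baseline_reference,
    featurize,
)
from .preprocessing import BIPOLAR_IDS, MonopolarRecording, preprocess
from .synthesis import (
    ARTIFACT_SUBTYPES,
    GroundTruth,
    SynthesisConfig,
    _band_power,
    _inject_event_artifact,
    contraction_waveform,
    pink_noise,
    synthesize_recording,
)

log = logging.getLogger("ehgkit")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    synthesis: SynthesisConfig = field(
        default_factory=lambda: SynthesisConfig(duration_s=1800.0)
    )
    input_path: Optional[str] = None          # use a recorded file instead
    annotations_path: Optional[str] = None
    # preprocessing
    filter_low: float = 0.1
    filter_high: float = 4.0
    filter_order: int = 5
    target_fs: float = 20.0
    # TOCO-like generation
    toco_band: tuple[float, float] = (0.34, 1.0)
    toco_window_s: float = 30.0
    toco_step_s: float = 0.25
    toco_methods: tuple[str, ...] = ("rms", "ufm")
    # baseline + detection
    baseline_window_s: float = 240.0
    baseline_frac: float = 0.10
    amp_factor: float = 2.0
    rel_frac: float = 0.25
    min_dur_s: float = 30.0
    iou_min: float = 0.3
    # features
    feature_method: str = "rms"
    sampen_m: int = 3
    sampen_r: float = 0.15
    tr_tau: int = 1
    n_surrogates: int = 100
    # classification
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    cv_reps: int = 50
    run_sfs: bool = False
    sfs_reps: int = 10
    min_class_rows: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthesis"]["interference_flags"] = sorted(
            self.synthesis.interference_flags
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthesis", None)
        cfg_kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                cfg_kwargs[f.name] = d[f.name]
        if syn is not None:
            syn = dict(syn)
            for key in ("contraction_duration_range", "contraction_band",
                        "artifact_duration_range", "step_duration_range",
                        "gain_range"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            if "artifact_types" in syn:
                syn["artifact_types"] = tuple(syn["artifact_types"])
            if "interference_flags" in syn:
                syn["interference_flags"] = frozenset(syn["interference_flags"])
            cfg_kwargs["synthesis"] = SynthesisConfig(**syn)
        for key in ("toco_band",):
            if key in cfg_kwargs:
                cfg_kwargs[key] = tuple(cfg_kwargs[key])
        for key in ("toco_methods", "classifiers"):
            if key in cfg_kwargs:
                cfg_kwargs[key] = tuple(cfg_kwargs[key])
        return cls(**cfg_kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    """Artifacts of one `run_pipeline` call."""

    outdir: Path
    segments: list[SegmentCandidate]
    feature_table: pd.DataFrame
    cv_reports: dict[str, CVReport]
    detection_counts: Optional[DetectionCounts]
    counts: dict


def run_pipeline(cfg: PipelineConfig, outdir) -> PipelineResult:
    """Run the full chain and write all artifacts under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    cfg.to_yaml(outdir / "config.yaml")

    # --- input ------------------------------------------------------------
    gt: Optional[GroundTruth] = None
    if cfg.input_path:
        rec = ehgio.read_recording(cfg.input_path)
        if cfg.annotations_path:
            gt = ehgio.read_annotations(cfg.annotations_path)
        log.info("loaded recording %s (%.0f s @ %.0f Hz)",
                 cfg.input_path, rec.duration_s, rec.fs)
    else:
        rec, gt = synthesize_recording(cfg.synthesis)
        log.info("simulated %.0f s recording with %d events",
                 cfg.synthesis.duration_s, len(gt.events))
    ehgio.write_recording(outdir / "recording.tsv", rec, meta)
    if gt is not None:
        ehgio.write_annotations(outdir / "annotations.tsv", gt, meta)

    # --- preprocessing ----------------------------------------------------
    bip = preprocess(rec, cfg.filter_low, cfg.filter_high,
                     cfg.filter_order, cfg.target_fs)
    ehgio.write_recording(outdir / "bipolar.tsv", bip, meta)

    # --- envelopes, baselines, detection ----------------------------------
    envdir = outdir / "envelopes"
    envdir.mkdir(exist_ok=True)
    all_segments: list[SegmentCandidate] = []
    envelopes: dict[tuple[str, str], TocoLikeEnvelope] = {}
    for cid in BIPOLAR_IDS:
        x = bip.channel(cid)
        filtered = uterine_band_filter(x, bip.fs, cfg.toco_band, cfg.filter_order)
        for method in cfg.toco_methods:
            env = tocolike(filtered, bip.fs, method, cfg.toco_window_s,
                           cfg.toco_step_s, cfg.toco_band,
                           source_channel=cid, prefilter=False)
            envelopes[(cid, method)] = env
            ehgio.write_envelope(envdir / f"{cid}_{method}.tsv", env, meta)
            bl = estimate_baseline(env, cfg.baseline_window_s, cfg.baseline_frac)
            segs = detect_segments(env, bl, cfg.amp_factor, cfg.rel_frac,
                                   cfg.min_dur_s, signal=x, fs=bip.fs,
                                   channel=cid)
            all_segments.extend(segs)
    counts: dict = {
        "segments_per_method": {
            m: sum(1 for s in all_segments if s.method == m)
            for m in cfg.toco_methods
        }
    }
    det_counts: Optional[DetectionCounts] = None
    if gt is not None:
        primary = [s for s in all_segments if s.method == cfg.feature_method]
        _, det_counts = match_segments_to_truth(primary, gt, cfg.iou_min)
        others = [s for s in all_segments if s.method != cfg.feature_method]
        if others:
            match_segments_to_truth(others, gt, cfg.iou_min)
        counts["detection"] = {
            "hits": det_counts.hits, "misses": det_counts.misses,
            "false_alarms": det_counts.false_alarms,
        }
    ehgio.write_segments(outdir / "segments.tsv", all_segments, meta)
    log.info("detected %d candidate segments", len(all_segments))

    # --- features ----------------------------------------------------------
    feature_segments = [s for s in all_segments if s.method == cfg.feature_method]
    rows = []
    excluded = 0
    rng = np.random.default_rng(cfg.seed)
    refs: dict[str, BaselineReference] = {}
    for cid in BIPOLAR_IDS:
        try:
            refs[cid] = extract_baseline_reference(
                bip.channel(cid), bip.fs, envelopes[(cid, cfg.feature_method)],
                frac=cfg.baseline_frac, window_s=cfg.baseline_window_s,
                channel=cid,
            )
        except ValueError as exc:
            log.warning("no baseline reference for %s: %s", cid, exc)
    for seg in feature_segments:
        ref = refs.get(seg.channel)
        if ref is None:
            excluded += 1
            continue
        sub_seed = int(rng.integers(2**31))
        try:
            fv = featurize(seg, ref, n_surrogates=cfg.n_surrogates,
                           seed=sub_seed, m=cfg.sampen_m, r=cfg.sampen_r,
                           tau=cfg.tr_tau)
        except FeatureError as exc:
            log.warning("segment %s @%.0fs excluded: %s",
                        seg.channel, seg.onset_s, exc)
            excluded += 1
            continue
        row = fv.as_dict()
        row["group_id"] = 0
        rows.append(row)
    counts["features_excluded"] = excluded
    table = pd.DataFrame(rows)
    if not table.empty and not np.all(np.isfinite(table[list(FEATURE_NAMES)])):
        bad = ~np.all(np.isfinite(table[list(FEATURE_NAMES)]), axis=1)
        log.warning("dropping %d rows with non-finite features", int(bad.sum()))
        table = table[~bad].reset_index(drop=True)
    ehgio.write_feature_table(outdir / "features.tsv", table, meta)

    # --- classification -----------------------------------------------------
    cv_reports: dict[str, CVReport] = {}
    labeled = table[table["label"].isin([LABEL_ARTIFACT, LABEL_CLEAN])] if (
        not table.empty
    ) else table
    enough = (
        not labeled.empty
        and (labeled["label"] == LABEL_ARTIFACT).sum() >= cfg.min_class_rows
        and (labeled["label"] == LABEL_CLEAN).sum() >= cfg.min_class_rows
    )
    if enough:
        feats = None
        if cfg.run_sfs:
            sfs = sequential_forward_selection(
                labeled, cfg.classifiers[0], reps=cfg.sfs_reps, seed=cfg.seed
            )
            feats = sfs.selected or None
            ehgio.write_json(outdir / "sfs.json",
                             {"selected": sfs.selected,
                              "error_trace": sfs.error_trace})
        for kind in cfg.classifiers:
            rep = repeated_two_fold_cv(labeled, kind, feats,
                                       reps=cfg.cv_reps, seed=cfg.seed)
            cv_reports[kind] = rep
            (outdir / f"cv_{kind}.txt").write_text(
                f"# config_hash={meta['config_hash']}\n" + rep.to_text()
            )
        ehgio.write_json(outdir / "cv_summary.json", {
            kind: {mname: list(rep.summary[mname])
                   for mname in rep.summary}
            for kind, rep in cv_reports.items()
        })
    else:
        log.info("too few labeled segments for cross-validation; skipping")
    ehgio.write_json(outdir / "counts.json", counts)
    return PipelineResult(outdir=outdir, segments=all_segments,
                          feature_table=table, cv_reports=cv_reports,
                          detection_counts=det_counts, counts=counts)


# ---------------------------------------------------------------------------
# direct window-level simulation
# ---------------------------------------------------------------------------

def simulate_labeled_windows(
    n_contraction: int,
    n_artifact: int,
    seed: int = 0,
    window_s: float = 60.0,
    snr_db: float = 14.0,
    noise_sigma: float = 5.0,
    artifact_subtypes: Sequence[str] = ARTIFACT_SUBTYPES,
    co_contraction_prob: float = 0.5,
    fs_raw: float = 500.0,
    target_fs: float = 20.0,
) -> tuple[list[SegmentCandidate], BaselineReference]:
    """Balanced contraction / artifact windows with exact labels.

    Each window is built like the full simulator -- pink-noise baseline plus
    a contraction burst and/or one artifact -- then run through the standard
    preprocessing chain and sliced to `window_s` seconds of bipolar channel
    B1 at the working rate.  Contraction bursts outlast the window slightly
    so the slice resembles a detector segment (the above-threshold core of a
    burst).  With probability `co_contraction_prob` an artifact window also
    holds a contraction, mirroring movement during contractions; such
    windows are labeled artifacted.  A quiet recording from the same
    generator provides the `BaselineReference`.
    """
    rng = np.random.default_rng(seed)
    pad = 30.0
    dur = window_s + 2 * pad
    nraw = int(round(dur * fs_raw))
    band = (0.34, 1.0)
    cfg = SynthesisConfig(
        duration_s=dur, fs_raw=fs_raw, snr_db=snr_db, noise_sigma=noise_sigma,
        contraction_rate=0.0, artifact_rate=0.0,
    )

    def make_noise() -> np.ndarray:
        return np.column_stack(
            [noise_sigma * pink_noise(rng, nraw, fs_raw) for _ in range(5)]
        )

    def add_contraction(mono: np.ndarray) -> None:
        c_dur = 1.4 * window_s
        onset = pad + window_s / 2 - c_dur / 2
        i0 = int(round(onset * fs_raw))
        m = int(round(c_dur * fs_raw))
        i1 = min(nraw, i0 + m)
        p_band = np.mean([_band_power(mono[:, c], fs_raw, band) for c in range(5)])
        target = p_band * 10.0 ** (snr_db / 10.0)
        burst = contraction_waveform(rng, i1 - i0, fs_raw, band, 5, cfg.shared_frac)
        gains = rng.uniform(*cfg.gain_range, size=5)
        mono[i0:i1] += np.sqrt(target) * burst * gains

    def finish(mono: np.ndarray, label: str, subtype: str = "") -> SegmentCandidate:
        bip = preprocess(MonopolarRecording(samples=mono, fs=fs_raw), target_fs=target_fs)
        x = bip.channel("B1")
        j0 = int(round(pad * target_fs))
        j1 = int(round((pad + window_s) * target_fs))
        seg = SegmentCandidate(
            channel="B1", method="sim", onset_s=pad, offset_s=pad + window_s,
            samples=x[j0:j1].copy(), fs=target_fs, label=label,
        )
        seg.subtype = subtype
        return seg

    windows: list[SegmentCandidate] = []
    for _ in range(n_contraction):
        mono = make_noise()
        add_contraction(mono)
        windows.append(finish(mono, LABEL_CLEAN))
    subtypes = list(artifact_subtypes)
    for k in range(n_artifact):
        mono = make_noise()
        if rng.uniform() < co_contraction_prob:
            add_contraction(mono)
        subtype = subtypes[k % len(subtypes)]
        a_dur = 0.8 * window_s
        a_onset = pad + 0.1 * window_s
        mono[:, 0] = _inject_event_artifact(
            mono[:, 0], fs_raw, subtype, a_onset, a_dur, cfg, rng
        )
        windows.append(finish(mono, LABEL_ARTIFACT, subtype))

    quiet = make_noise()
    bip_quiet = preprocess(MonopolarRecording(samples=quiet, fs=fs_raw), target_fs=target_fs)
    g = int(round(pad * target_fs))
    ref = BaselineReference(samples=bip_quiet.channel("B1")[g:-g], channel="B1")
    return windows, ref


def simulate_feature_table(
    n_contraction: int,
    n_artifact: int,
    seed: int = 0,
    n_surrogates: int = 100,
    n_groups: int = 12,
    **window_kwargs,
) -> pd.DataFrame:
    """Labeled feature table from `simulate_labeled_windows`.

    Rows carry the 11 features, the label, the artifact subtype and a
    synthetic ``group_id`` (windows dealt round-robin over `n_groups`
    pseudo-recordings, enabling leakage-guarded holdout splits).
    """
    windows, ref = simulate_labeled_windows(n_contraction, n_artifact,
                                            seed=seed, **window_kwargs)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, seg in enumerate(windows):
        fv = featurize(seg, ref, n_surrogates=n_surrogates,
                       seed=int(rng.integers(2**31)))
        row = fv.as_dict()
        row["subtype"] = getattr(seg, "subtype", "")
        row["group_id"] = i % n_groups
        rows.append(row)
    return pd.DataFrame(rows)
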