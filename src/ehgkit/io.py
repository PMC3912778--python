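"""Readers and writers for the package's plain-text interchange formats.

Everything is tab-separated text with ``#`` header lines carrying metadata
(sampling rate, channel ids, provenance), so runs are diffable and
reproducible byte-for-byte.  EDF input is supported through :mod:`mne`
when that package is available.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .detection import SegmentCandidate
from .envelopes import TocoLikeEnvelope
from .preprocessing import (
    BIPOLAR_IDS,
    MONOPOLAR_IDS,
    BipolarRecording,
    MonopolarRecording,
)
from .synthesis import Event, GroundTruth

PathLike = Union[str, Path]
_FLOAT_FMT = "%.8g"


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}={v}\n")


def _read_header(path: PathLike) -> tuple[dict, int]:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, skip


def write_recording(
    path: PathLike,
    rec: Union[MonopolarRecording, BipolarRecording],
    extra_meta: Optional[dict] = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {"fs": repr(rec.fs),
                           "channels": ",".join(rec.channel_ids),
                           **(extra_meta or {})})
        fh.write("\t".join(rec.channel_ids) + "\n")
        np.savetxt(fh, rec.samples, fmt=_FLOAT_FMT, delimiter="\t")


def read_recording(path: PathLike) -> Union[MonopolarRecording, BipolarRecording]:
    meta, skip = _read_header(path)
    fs = float(meta["fs"])
    channels = tuple(meta["channels"].split(","))
    data = np.loadtxt(path, skiprows=skip + 1, delimiter="\t", ndmin=2)
    if channels == MONOPOLAR_IDS:
        return MonopolarRecording(samples=data, fs=fs)
    if channels == BIPOLAR_IDS:
        return BipolarRecording(samples=data, fs=fs)
    raise ValueError(f"unrecognised channel set {channels}")


def read_edf(path: PathLike, channel_map: Sequence[str] = MONOPOLAR_IDS) -> MonopolarRecording:
    """Load a monopolar recording from an EDF file (requires ``mne``).

    `channel_map` names the EDF channels that correspond, in order, to
    electrodes M1..M5.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [raw.ch_names.index(c) for c in channel_map] if set(channel_map) <= set(
        raw.ch_names
    ) else list(range(5))
    data = raw.get_data(picks=picks).T
    return MonopolarRecording(samples=data, fs=float(raw.info["sfreq"]))


def write_annotations(path: PathLike, gt: GroundTruth, extra_meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {"duration_s": repr(gt.duration_s), **(extra_meta or {})})
        fh.write("kind\tchannels\tonset_s\toffset_s\tsubtype\n")
        for ev in gt.events:
            fh.write(
                f"{ev.kind}\t{'|'.join(ev.channels)}\t{ev.onset_s:.4f}\t"
                f"{ev.offset_s:.4f}\t{ev.subtype}\n"
            )


def read_annotations(path: PathLike) -> GroundTruth:
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, keep_default_na=False)
    events = [
        Event(
            kind=row["kind"],
            channels=tuple(str(row["channels"]).split("|")) if row["channels"] else (),
            onset_s=float(row["onset_s"]),
            offset_s=float(row["offset_s"]),
            subtype=str(row["subtype"]),
        )
        for _, row in df.iterrows()
    ]
    return GroundTruth(events=events, duration_s=float(meta["duration_s"]))


def write_envelope(path: PathLike, env: TocoLikeEnvelope, extra_meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {
            "method": env.method, "channel": env.source_channel or "",
            "window_s": repr(env.window_s), "step_s": repr(env.step_s),
            "t0_s": repr(env.t0_s), **(extra_meta or {}),
        })
        fh.write("t_s\tvalue\n")
        np.savetxt(fh, np.column_stack([env.times, env.values]),
                   fmt=_FLOAT_FMT, delimiter="\t")


def read_envelope(path: PathLike) -> TocoLikeEnvelope:
    meta, skip = _read_header(path)
    data = np.loadtxt(path, skiprows=skip + 1, delimiter="\t", ndmin=2)
    return TocoLikeEnvelope(
        values=data[:, 1], step_s=float(meta["step_s"]),
        window_s=float(meta["window_s"]), method=meta["method"],
        source_channel=meta.get("channel") or None, t0_s=float(meta["t0_s"]),
    )


def write_segments(
    path: PathLike, segs: Sequence[SegmentCandidate], extra_meta: Optional[dict] = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, extra_meta or {})
        fh.write("channel\tmethod\tonset_s\toffset_s\tlabel\n")
        for s in segs:
            fh.write(f"{s.channel}\t{s.method}\t{s.onset_s:.4f}\t{s.offset_s:.4f}\t{s.label}\n")


def read_segments(path: PathLike) -> list[SegmentCandidate]:
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, keep_default_na=False)
    return [
        SegmentCandidate(
            channel=row["channel"], method=row["method"],
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            label=row["label"],
        )
        for _, row in df.iterrows()
    ]


def write_feature_table(path: PathLike, table: pd.DataFrame, extra_meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, extra_meta or {})
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: PathLike) -> pd.DataFrame:
    meta, skip = _read_header(path)
    return pd.read_csv(path, sep="\t", skiprows=skip)


def write_json(path: PathLike, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
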