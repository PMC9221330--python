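"""Readers and writers for the plain-text artifact formats.

Formats (all diffable text):

* channel CSV  — ``# subject=<id> kind=ECG rate=512`` header line, then
  ``time_s,value`` rows;
* labels CSV   — ``start_s,end_s,label`` rows (label is the behavior name);
* feature TSV  — ``subject<TAB>window_start_s<TAB><28 features><TAB>label``;
* difficulty CSV — one row per subject, one column per behavior.
"""
from __future__ import annotations

import importlib.resources
import logging
import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model import (
    BehaviorLabel,
    ChannelKind,
    ChannelRecording,
    DifficultyTable,
    LabeledRecordingSet,
    LabelTrack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_channel",
    "write_channel",
    "read_label_track",
    "write_label_track",
    "read_recording_set",
    "write_recording_set",
    "read_feature_matrix",
    "write_feature_matrix",
    "load_difficulty_fixture",
    "read_difficulty_table",
    "write_difficulty_table",
]

# shortest exact representation: round trips bit-for-bit, and certainly
# to the 12 significant digits the format guarantees
_FLOAT_FMT = "%.17g"


def write_channel(rec: ChannelRecording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# subject={rec.subject_id} kind={rec.kind.value} "
            f"rate={rec.rate:.12g} start={rec.start_time:.12g}\n"
        )
        fh.write("time_s,value\n")
        times = rec.times
        for t, v in zip(times, rec.samples):
            fh.write(f"{t:.12g},{v:.17g}\n")


def read_channel(path: str | Path) -> ChannelRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing channel header line")
    # values may contain spaces (subject ids); keys are \w+ followed by '='
    meta = {
        m.group(1): m.group(2).strip()
        for m in re.finditer(r"(\w+)=(.*?)(?=\s+\w+=|\s*$)", header[1:].strip())
    }
    kind = ChannelKind(meta["kind"])
    rate = float(meta["rate"])
    start = float(meta.get("start", 0.0))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return ChannelRecording(
        subject_id=meta.get("subject", ""),
        kind=kind,
        rate=rate,
        samples=df["value"].to_numpy(dtype=float),
        start_time=start,
    )


def write_label_track(track: LabelTrack, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("start_s,end_s,label\n")
        for s, e, lab in track.segments:
            fh.write(f"{s:.12g},{e:.12g},{lab.to_string()}\n")


def read_label_track(path: str | Path) -> LabelTrack:
    df = pd.read_csv(path)
    segments = [
        (float(r.start_s), float(r.end_s), BehaviorLabel.from_string(str(r.label)))
        for r in df.itertuples()
    ]
    return LabelTrack(segments)


def read_recording_set(
    paths: Mapping[ChannelKind, str | Path], labels_path: str | Path
) -> LabeledRecordingSet:
    """Load one subject's five channel files plus the labels file."""
    missing = [k for k in ChannelKind if k not in paths or not Path(paths[k]).exists()]
    if missing:
        raise ValueError(
            "incomplete modality set: missing "
            + ", ".join(k.value for k in missing)
        )
    channels = {k: read_channel(paths[k]) for k in ChannelKind}
    subject_ids = {c.subject_id for c in channels.values()}
    if len(subject_ids) != 1:
        raise ValueError(f"mixed subject ids in channel files: {subject_ids}")
    track = read_label_track(labels_path)
    return LabeledRecordingSet(
        subject_id=subject_ids.pop(), channels=channels, label_track=track
    )


def write_recording_set(rset: LabeledRecordingSet, out_dir: str | Path) -> dict:
    """Write one file per channel plus a labels file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = rset.subject_id.replace(" ", "_")
    paths: dict = {}
    for kind, rec in rset.channels.items():
        p = out_dir / f"{sid}_{kind.value}.csv"
        write_channel(rec, p)
        paths[kind] = p
    labels_path = out_dir / f"{sid}_labels.csv"
    write_label_track(rset.label_track, labels_path)
    paths["labels"] = labels_path
    logger.info("wrote recording set %s (%d channels)", rset.subject_id, len(rset.channels))
    return paths


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Serialize a FeatureMatrix as TSV; exact round trip to 12 sig. digits."""
    if len(matrix.frame) == 0:
        raise ValueError("empty matrix")
    df = matrix.frame.copy()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_feature_matrix(path: str | Path):
    from .features import FEATURE_NAMES, FeatureMatrix

    df = pd.read_csv(
        path, sep="\t", dtype={"subject": str, "label": str}, float_precision="round_trip"
    )
    expected = ["subject", "window_start_s", *FEATURE_NAMES, "label"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    return FeatureMatrix(frame=df[expected + [c for c in df.columns if c not in expected]])


def read_difficulty_table(path: str | Path) -> DifficultyTable:
    df = pd.read_csv(path, index_col=0)
    return DifficultyTable(df)


def write_difficulty_table(table: DifficultyTable, path: str | Path) -> None:
    out = table.ratings.copy()
    out.index.name = "subject"
    out.to_csv(path)


def load_difficulty_fixture() -> DifficultyTable:
    """The packaged 14-subject x 6-behavior subjective rating table."""
    ref = importlib.resources.files("physiofuse") / "data" / "difficulty_ratings.csv"
    with importlib.resources.as_file(ref) as p:
        return read_difficulty_table(p)
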