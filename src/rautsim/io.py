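"""File formats: stream logs, interval records, results tables, run manifests.

Streams are onset/offset tables (CSV, header ``event,onset_s,offset_s``),
which also lets real continuous-recording logs be loaded and degraded into
interval records.  Interval records are ``interval,mark`` CSVs with a JSON
sidecar carrying procedure, tau, n and session length.  A run manifest
(JSON) snapshots config, seed, version and outputs so any results file can
be re-created bit-identically.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .arp_core import BehaviorStream
from .recorders import IntervalRecord


class StreamValidationError(ValueError):
    """Raised when an onset/offset table is not a valid behavior stream."""


def write_stream_csv(stream: BehaviorStream, path) -> None:
    df = pd.DataFrame({
        "event": range(1, stream.n_events + 1),
        "onset_s": stream.onsets,
        "offset_s": stream.offsets,
    })
    df.to_csv(path, index=False)


def read_stream_csv(path, session_length: float | None = None) -> BehaviorStream:
    """Load an onset/offset CSV as a validated stream.

    ``session_length`` defaults to the last offset.  Malformed rows
    (offset <= onset, overlap with the previous event, negative times) are
    reported with their row numbers.
    """
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise StreamValidationError(
            f"stream CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise StreamValidationError("stream CSV contains no events")
    bad = []
    prev_off = None
    for row in df.itertuples():
        i = row.Index + 2  # 1-based, after header
        if not row.offset_s > row.onset_s:
            bad.append(f"row {i}: offset {row.offset_s} <= onset {row.onset_s}")
        elif row.onset_s < 0:
            bad.append(f"row {i}: negative onset {row.onset_s}")
        elif prev_off is not None and row.onset_s <= prev_off:
            bad.append(f"row {i}: onset {row.onset_s} overlaps previous offset {prev_off}")
        prev_off = row.offset_s
    if bad:
        raise StreamValidationError("invalid event rows:\n" + "\n".join(bad))
    L = float(session_length) if session_length is not None else float(df["offset_s"].iloc[-1])
    try:
        return BehaviorStream(
            session_length=L,
            onsets=df["onset_s"].to_numpy(float),
            offsets=df["offset_s"].to_numpy(float),
        )
    except ValueError as exc:
        raise StreamValidationError(str(exc)) from exc


def write_interval_record(rec: IntervalRecord, path) -> None:
    """Write marks CSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({
        "interval": range(1, rec.n + 1), "mark": rec.marks
    }).to_csv(path, index=False)
    meta = {
        "procedure": rec.procedure, "tau": rec.tau, "n": rec.n,
        "session_length": rec.session_length,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def read_interval_record(path) -> IntervalRecord:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    marks = pd.read_csv(path)["mark"].to_numpy()
    return IntervalRecord(
        procedure=meta["procedure"], tau=meta["tau"],
        session_length=meta["session_length"], marks=marks,
    )


def write_manifest(path, command: str, config: dict, seed: int, outputs) -> None:
    """Snapshot everything needed to re-run a command bit-identically."""
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
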