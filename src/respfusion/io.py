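"""Readers and writers for the delimited-text recording layout.

A recording on disk is a directory holding one delimited text file per
sampling-rate group (header row with channel names) plus a ``recording.json``
sidecar with subject, scenario and the per-channel sampling rates.  The reader
also accepts foreign directories / single files when given an explicit
column-to-channel mapping, since deposited ``.txt`` layouts vary in dialect.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ChannelTrace, MultimodalRecording, PipelineConfig, RespFusionError

log = logging.getLogger(__name__)

SIDECAR_NAME = "recording.json"
_DELIMS = {"\t": "\t", ",": ",", ";": ";"}


def _detect_delimiter(path: Path) -> str:
    """Pick the delimiter among tab/comma/semicolon/whitespace from the header."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                counts = {d: line.count(d) for d in _DELIMS}
                best = max(counts, key=counts.get)  # type: ignore[arg-type]
                return best if counts[best] > 0 else r"\s+"
    raise RespFusionError(f"{path}: file is empty")


def _read_table(path: Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RespFusionError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise RespFusionError(f"{path}: missing value at row {row}, column {col!r}")
        out[col] = converted.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _fs_tag(fs: float) -> str:
    s = f"{fs:g}".replace(".", "p")
    return re.sub(r"[^0-9a-zA-Z_p]", "", s)


def write_recording(rec: MultimodalRecording, path: str | Path) -> list[Path]:
    """Write ``rec`` as delimited text plus a JSON metadata sidecar.

    One tab-separated file is written per sampling-rate group.  Returns the
    list of files written (data files first, sidecar last).
    """
    if not rec.channels:
        raise RespFusionError("nothing to write: recording has no channels")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    groups: dict[float, list[str]] = {}
    for name, trace in rec.channels.items():
        groups.setdefault(float(trace.fs), []).append(name)

    written: list[Path] = []
    files_meta = []
    for fs, names in sorted(groups.items()):
        fname = f"data_{_fs_tag(fs)}hz.tsv"
        cols = {n: rec.channels[n].samples for n in names}
        df = pd.DataFrame(cols)
        df.to_csv(path / fname, sep="\t", index=False, float_format="%.12g")
        files_meta.append({"file": fname, "fs": fs, "channels": names})
        written.append(path / fname)

    sidecar = {
        "subject_id": rec.subject_id,
        "scenario": rec.scenario,
        "files": files_meta,
    }
    with open(path / SIDECAR_NAME, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    written.append(path / SIDECAR_NAME)
    return written


def _read_with_sidecar(path: Path, delimiter: str | None) -> MultimodalRecording:
    with open(path / SIDECAR_NAME) as fh:
        meta = json.load(fh)
    channels: dict[str, ChannelTrace] = {}
    for entry in meta["files"]:
        df = _read_table(path / entry["file"], delimiter)
        for name in entry["channels"]:
            if name not in df.columns:
                raise RespFusionError(
                    f"missing mandatory channel {name!r} in {entry['file']}"
                )
            channels[name] = ChannelTrace(name, df[name].to_numpy(), float(entry["fs"]))
        extra = set(df.columns) - set(entry["channels"])
        if extra:
            log.warning("%s: ignoring unmapped columns %s", entry["file"], sorted(extra))
    return MultimodalRecording(meta["subject_id"], meta["scenario"], channels)


def read_recording(
    path: str | Path,
    config: PipelineConfig | None = None,
    *,
    fs: float | None = None,
    subject_id: str = "unknown",
    scenario: str = "city",
) -> MultimodalRecording:
    """Read a recording from a directory or a single delimited file.

    If ``path`` contains a ``recording.json`` sidecar (the layout produced by
    :func:`write_recording`) it is authoritative.  Otherwise ``config`` must
    provide ``channel_map`` (column name -> channel name) and ``fs`` the
    sampling rate of the file(s); unmapped columns are ignored with a warning
    and a mapped column missing from the data is an error.
    """
    path = Path(path)
    config = config or PipelineConfig()
    delimiter = config.delimiter

    if path.is_dir() and (path / SIDECAR_NAME).exists():
        return _read_with_sidecar(path, delimiter)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".txt", ".tsv", ".csv"}
        )
        if not files:
            raise RespFusionError(f"{path}: no delimited text files found")
    else:
        if not path.exists():
            raise RespFusionError(f"{path}: no such file")
        files = [path]

    if not config.channel_map:
        raise RespFusionError(
            "no recording.json sidecar found and config.channel_map is empty; "
            "provide an explicit column-to-channel mapping"
        )
    if fs is None:
        raise RespFusionError("fs is required when reading without a sidecar")

    channels: dict[str, ChannelTrace] = {}
    seen_cols: set[str] = set()
    for f in files:
        df = _read_table(f, delimiter)
        for col in df.columns:
            if col in config.channel_map:
                name = config.channel_map[col]
                channels[name] = ChannelTrace(name, df[col].to_numpy(), fs)
                seen_cols.add(col)
            else:
                log.warning("%s: ignoring unmapped column %r", f, col)
    missing = set(config.channel_map) - seen_cols
    if missing:
        raise RespFusionError(
            "missing mandatory channel(s): "
            + ", ".join(sorted(config.channel_map[c] for c in missing))
        )
    return MultimodalRecording(subject_id, scenario, channels)
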