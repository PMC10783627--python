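"""Delimited-text formats: traces, key-point tables, session logs, config.

Everything is plain UTF-8 comma-separated text with '.' decimals so that
raw data and logs stay auditable without special tooling.  Traces
round-trip losslessly (values are written with 17 significant digits) and
the reader verifies uniform sampling to within 1 ppm of the declared rate.
Session logs are append-only and rectangular: censored trials carry the
cutoff as their latency, never a blank.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .records import EXTRA_COLUMNS, SESSION_LOG_COLUMNS, TrialRecord, config_hash
from .rig_sim import KeyPointStream
from .signals import SignalTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_keypoints",
    "read_keypoints",
    "write_session_log",
    "read_session_log",
    "load_config",
    "config_hash",
]

PathLike = Union[str, Path]

_TRACE_HEADER = "# nocirig-trace units={units} fs={fs!r} t0={t0!r}"


def write_trace(trace: SignalTrace, path: PathLike) -> Path:
    """Write a trace as two-column delimited text with a metadata header."""
    path = Path(path)
    lines = [_TRACE_HEADER.format(units=trace.units, fs=trace.fs, t0=trace.t0)]
    lines.append("time_ms,value")
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{t:.17g},{v:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_trace(path: PathLike) -> SignalTrace:
    """Read a trace file; validates header and uniform sampling (1 ppm)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("# nocirig-trace"):
        raise ValueError(f"{path}: missing trace header")
    meta = dict(tok.split("=", 1) for tok in header.split()[2:])
    if "units" not in meta:
        raise ValueError(f"{path}: header missing units")
    if "fs" not in meta:
        raise ValueError(f"{path}: header missing fs")
    fs = float(meta["fs"])
    t0 = float(meta.get("t0", "0.0"))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != ["time_ms", "value"]:
        raise ValueError(f"{path}: expected columns time_ms,value")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = 1000.0 / fs
    if t.size > 1:
        dev = np.abs(np.diff(t) - dt)
        bad = np.flatnonzero(dev > dt * 1e-6)
        if bad.size:
            raise ValueError(
                f"{path}: non-uniform sampling at index {int(bad[0]) + 1} "
                f"(interval {t[bad[0] + 1] - t[bad[0]]:g} ms, expected {dt:g} ms)"
            )
    if abs(t[0] - t0) > max(1e-9, abs(t0) * 1e-6):
        raise ValueError(f"{path}: first timestamp {t[0]!r} disagrees with header t0={t0!r}")
    return SignalTrace(df["value"].to_numpy(dtype=float), fs=fs, t0=t0, units=meta["units"])


def write_keypoints(stream: KeyPointStream, path: PathLike) -> Path:
    """Write a key-point stream as long-format delimited text."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# nocirig-keypoints fps={stream.fps!r} arena={stream.arena[0]}x{stream.arena[1]}\n")
        stream.table.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_keypoints(path: PathLike) -> KeyPointStream:
    """Read a key-point table written by :func:`write_keypoints`."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("# nocirig-keypoints"):
        raise ValueError(f"{path}: missing key-point header")
    meta = dict(tok.split("=", 1) for tok in header.split()[2:])
    fps = float(meta["fps"])
    w, h = (int(v) for v in meta["arena"].split("x"))
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    return KeyPointStream(table=table, fps=fps, arena=(w, h))


# ---------------------------------------------------------------------------
# session log
# ---------------------------------------------------------------------------

LOG_COLUMNS = SESSION_LOG_COLUMNS + EXTRA_COLUMNS


def write_session_log(
    records: Sequence[TrialRecord], path: PathLike, check_paths: bool = True
) -> Path:
    """Serialize trial records with the fixed column order.

    Refuses duplicate (mouse_id, timestamp) pairs and — unless
    ``check_paths`` is disabled — records whose linked trace/key-point
    files do not exist.
    """
    path = Path(path)
    seen = set()
    for rec in records:
        key = (rec.mouse_id, rec.timestamp)
        if key in seen:
            raise ValueError(f"duplicate trial {key}")
        seen.add(key)
        if check_paths:
            for p in (rec.trace_path, rec.keypoints_path):
                if p and not os.path.exists(p):
                    raise ValueError(f"linked file missing: {p}")
    rows = [dataclasses.asdict(rec) for rec in records]
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_session_log(path: PathLike) -> list[TrialRecord]:
    """Read a session log back into trial records (lossless round-trip)."""
    df = pd.read_csv(
        Path(path), keep_default_na=False, na_values=[""], float_precision="round_trip"
    )
    if list(df.columns) != LOG_COLUMNS:
        raise ValueError(f"{path}: unexpected session-log columns {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TrialRecord(
                mouse_id=str(row["mouse_id"]),
                timestamp=str(row["timestamp"]),
                modality=str(row["modality"]),
                waveform=str(row["waveform"]),
                intensity=float(row["intensity"]),
                cutoff_ms=float(row["cutoff_ms"]),
                outcome=str(row["outcome"]),
                latency_ms=float(row["latency_ms"]),
                censored=_as_bool(row["censored"]),
                threshold_mN=float(row["threshold_mN"]),
                seed=int(row["seed"]),
                config_hash=str(row["config_hash"]) if str(row["config_hash"]) != "nan" else "",
                trace_path=_as_str(row["trace_path"]),
                keypoints_path=_as_str(row["keypoints_path"]),
                stim_duration_ms=float(row["stim_duration_ms"]),
                aim_time_ms=float(row["aim_time_ms"]),
                true_latency_ms=float(row["true_latency_ms"]),
            )
        )
    return out


def _as_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "1")


def _as_str(v) -> str:
    s = str(v)
    return "" if s in ("nan", "") else s


def session_log_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (same columns as the log file)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=LOG_COLUMNS)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: PathLike) -> dict:
    """Load a flat key-value YAML config file."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
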