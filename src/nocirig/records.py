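"""Trial records and configuration hashing.

One :class:`TrialRecord` is the unit of the session log: the metadata
(mouse, time, stimulus parameters), the measurement (outcome, latency,
censoring, mechanical threshold), the seeds and config hash needed to
reproduce the trial, and paths to the linked raw-data files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

__all__ = ["TrialRecord", "SESSION_LOG_COLUMNS", "config_hash"]

#: fixed session-log column order (leading columns; extra trial metadata
#: columns follow)
SESSION_LOG_COLUMNS = [
    "mouse_id",
    "timestamp",
    "modality",
    "waveform",
    "intensity",
    "cutoff_ms",
    "outcome",
    "latency_ms",
    "censored",
    "threshold_mN",
    "seed",
    "config_hash",
    "trace_path",
    "keypoints_path",
]

#: trailing metadata columns appended after the fixed block
EXTRA_COLUMNS = ["stim_duration_ms", "aim_time_ms", "true_latency_ms"]


def config_hash(cfg: dict) -> str:
    """Stable short hash of a flat configuration mapping.

    Keys are sorted and values serialized as JSON, so identical configs
    hash identically regardless of insertion order.
    """
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the session log.

    ``outcome`` is one of ``detected`` / ``censored`` / ``skipped``.
    Censored trials carry ``latency_ms == cutoff_ms`` with
    ``censored=True`` (never a blank), keeping the log rectangular.
    ``true_latency_ms`` is the simulator ground truth where known (NaN for
    data that did not come from the virtual rig).
    """

    mouse_id: str
    timestamp: str
    modality: str
    waveform: str
    intensity: float
    cutoff_ms: float
    outcome: str
    latency_ms: float
    censored: bool
    threshold_mN: float = math.nan
    seed: int = 0
    config_hash: str = ""
    trace_path: str = ""
    keypoints_path: str = ""
    stim_duration_ms: float = math.nan
    aim_time_ms: float = math.nan
    true_latency_ms: float = math.nan

    def __post_init__(self) -> None:
        if self.outcome not in ("detected", "censored", "skipped"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.censored != (self.outcome == "censored"):
            raise ValueError("censored flag must match outcome 'censored'")
        if self.outcome == "censored" and self.latency_ms != self.cutoff_ms:
            raise ValueError("censored trials must report latency at the cutoff")
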