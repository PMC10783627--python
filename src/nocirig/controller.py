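"""Automated aiming and closed-loop trial control.

The rig centers the stimulated paw in the substage camera frame by driving
x/y linear actuators with velocities proportional to the pixel error
between the tracked paw and the frame-center crosshair.  Proportional
control slows the approach near the target and prevents overshoot.  Once
the paw sits within a small deadband (3 px) of the crosshair, a settle
timer runs; if the paw stays put for the settle period (2 s) the stimulus
fires, and withdrawal is detected in real time so the stimulus can be
terminated the moment the response is confirmed.  A give-up timer skips
mice that are too active to stimulate reliably.  Sessions interleave
trials across mice so that each mouse's inter-stimulus interval is spent
testing its neighbors, with per-round randomized ordering.

Everything here runs in discrete time at the video frame interval
(33 ms at 30 fps); the actuator is modeled as an ideal velocity follower,
hardware latencies being out of scope.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import TrialRecord, config_hash
from .rig_sim import TARGET_PART, KeyPointStream, VirtualRig
from .signals import (
    DetectionConfig,
    StimulusEvent,
    StreamingWithdrawalDetector,
)

__all__ = [
    "ControllerConfig",
    "AimingState",
    "AimingOutcome",
    "SessionPlan",
    "pixel_error",
    "controller_step",
    "run_aiming",
    "run_trial",
    "run_session",
]

PHASES = ("AIMING", "SETTLING", "STIMULATING", "DONE", "SKIPPED")


@dataclass(frozen=True)
class ControllerConfig:
    """Aiming-loop parameters.

    ``gain`` scales the pixel error into an actuator velocity (px/step);
    ``max_speed`` clamps it.  ``deadband`` (px, default 3) is the
    tolerance within which no motion command is issued; by default it is
    applied per-axis (max-norm), switchable to Euclidean via ``norm``.
    ``settle_period`` (ms, default 2000) is the uninterrupted in-deadband
    time required before stimulating; ``giveup_period`` bounds the whole
    attempt.  Key points with confidence below ``min_confidence`` count as
    target-lost: the stage holds position and the settle timer resets.
    """

    gain: float = 0.5
    max_speed: float = 50.0
    deadband: float = 3.0
    settle_period: float = 2000.0
    giveup_period: float = 30000.0
    frame_interval: float = 33.0
    norm: str = "max"
    min_confidence: float = 0.5
    crosshair: tuple[float, float] = (320.0, 240.0)

    def __post_init__(self) -> None:
        if not (self.gain > 0):
            raise ValueError("gain must be positive")
        if not (self.deadband > 0):
            raise ValueError("deadband must be positive")
        if not (self.settle_period > 0):
            raise ValueError("settle_period must be positive")
        if not (self.giveup_period > 0):
            raise ValueError("giveup_period must be positive")
        if self.norm not in ("max", "euclid"):
            raise ValueError("norm must be 'max' or 'euclid'")

    def error_norm(self, error: tuple[float, float]) -> float:
        dx, dy = error
        if self.norm == "max":
            return max(abs(dx), abs(dy))
        return math.hypot(dx, dy)


@dataclass(frozen=True)
class AimingState:
    """One tick of the aiming state machine."""

    phase: str = "AIMING"
    error: tuple[float, float] = (0.0, 0.0)
    settle_elapsed: float = 0.0
    total_elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class AimingOutcome:
    """Result of one aiming attempt."""

    outcome: str  # "STIMULATE" or "SKIPPED"
    time_ms: float  # virtual time at decision
    history: tuple[AimingState, ...]


@dataclass(frozen=True)
class SessionPlan:
    """Multi-mouse session schedule.

    ``interval`` (s) is the minimum time between consecutive stimulus
    onsets for the same mouse.  With ``interleave`` the other mice are
    tested during that interval; ``randomize`` shuffles the order each
    round with the plan seed.
    """

    mouse_ids: tuple[str, ...]
    trials_per_mouse: int = 1
    interval: float = 60.0
    seed: int = 0
    interleave: bool = True
    randomize: bool = True

    def __post_init__(self) -> None:
        if len(self.mouse_ids) < 1:
            raise ValueError("plan requires at least one mouse")
        if len(set(self.mouse_ids)) != len(self.mouse_ids):
            raise ValueError("mouse IDs must be unique")
        if not (self.interval > 0):
            raise ValueError("inter-stimulus interval must be positive")
        if self.trials_per_mouse < 1:
            raise ValueError("trials_per_mouse must be >= 1")


def pixel_error(
    target: tuple[float, float], crosshair: tuple[float, float]
) -> tuple[float, float]:
    """Pixel error (dx, dy) = target - crosshair, image convention (y down)."""
    tx, ty = target
    cx, cy = crosshair
    if not all(math.isfinite(v) for v in (tx, ty, cx, cy)):
        raise ValueError("coordinates must be finite")
    return (tx - cx, ty - cy)


def controller_step(
    state: AimingState, error: tuple[float, float], cfg: ControllerConfig
) -> tuple[AimingState, tuple[float, float]]:
    """Advance the aiming state machine one frame.

    Inside the deadband: zero velocity, the settle timer accrues.  Outside:
    the settle timer resets and the commanded velocity is the clamped
    proportional term ``clamp(gain * error, max_speed)`` directed to reduce
    the error.  The total-elapsed clock always advances one frame.
    """
    total = state.total_elapsed + cfg.frame_interval
    if cfg.error_norm(error) <= cfg.deadband:
        new = AimingState("SETTLING", error, state.settle_elapsed + cfg.frame_interval, total)
        return new, (0.0, 0.0)
    vx = float(np.clip(cfg.gain * error[0], -cfg.max_speed, cfg.max_speed))
    vy = float(np.clip(cfg.gain * error[1], -cfg.max_speed, cfg.max_speed))
    return AimingState("AIMING", error, 0.0, total), (vx, vy)


def run_aiming(
    stream: KeyPointStream,
    cfg: ControllerConfig = ControllerConfig(),
    target_part: str = TARGET_PART,
) -> AimingOutcome:
    """Replay a key-point stream through the aiming loop.

    The stage offset is integrated from the commanded velocities (ideal
    follower); the on-screen target position is the tracked paw minus the
    stage offset.  Returns STIMULATE once the settle timer reaches the
    settle period, or SKIPPED once the give-up timer expires (or the
    stream ends first).
    """
    track = stream.part_track(target_part)
    if track.empty:
        raise ValueError("empty key-point stream")
    xs = track["x_px"].to_numpy()
    ys = track["y_px"].to_numpy()
    conf = track["confidence"].to_numpy()
    ox = oy = 0.0
    state = AimingState()
    history: list[AimingState] = []
    last_error = (math.nan, math.nan)
    for k in range(len(track)):
        if conf[k] < cfg.min_confidence:
            # target lost: hold position, settle resets, clock advances
            state = AimingState(
                "AIMING", last_error, 0.0, state.total_elapsed + cfg.frame_interval
            )
            v = (0.0, 0.0)
        else:
            err = pixel_error((xs[k] - ox, ys[k] - oy), cfg.crosshair)
            last_error = err
            state, v = controller_step(state, err, cfg)
        ox += v[0]
        oy += v[1]
        history.append(state)
        if state.settle_elapsed >= cfg.settle_period:
            return AimingOutcome("STIMULATE", state.total_elapsed, tuple(history))
        if state.total_elapsed >= cfg.giveup_period:
            return AimingOutcome("SKIPPED", state.total_elapsed, tuple(history))
    return AimingOutcome("SKIPPED", state.total_elapsed, tuple(history))


def run_trial(
    rig: VirtualRig,
    stim: StimulusEvent,
    cfg: ControllerConfig = ControllerConfig(),
    det: DetectionConfig = DetectionConfig(),
    seed: Optional[int] = None,
    timestamp: str = "1970-01-01T00:00:00",
) -> TrialRecord:
    """One fully automated trial on a virtual rig.

    Aim at the key-point stream; if aiming succeeds, fire the stimulus,
    stream the simulated reflectance through the real-time detector, and
    terminate the stimulus at the detection event (latency + persistence
    lag) or at the cutoff.  A skipped aiming attempt produces a record
    with outcome ``skipped`` and no stimulus.
    """
    trial_seed = rig.seed if seed is None else seed
    stream = rig.keypoint_stream(duration=cfg.giveup_period + 2000.0, seed=trial_seed)
    aim = run_aiming(stream, cfg)
    cfg_hash = config_hash(
        {**dataclasses.asdict(cfg), **dataclasses.asdict(det)}
    )
    base = dict(
        mouse_id=rig.mouse_id,
        timestamp=timestamp,
        modality=stim.modality,
        waveform=stim.waveform,
        intensity=stim.intensity,
        cutoff_ms=stim.cutoff,
        seed=trial_seed,
        config_hash=cfg_hash,
    )
    if aim.outcome == "SKIPPED":
        return TrialRecord(
            outcome="skipped",
            latency_ms=math.nan,
            censored=False,
            threshold_mN=math.nan,
            stim_duration_ms=0.0,
            aim_time_ms=aim.time_ms,
            **base,
        )
    trace, truth = rig.reflectance_trial(stim, seed=trial_seed)
    detector = StreamingWithdrawalDetector(stim, det, fs=rig.fs)
    result = None
    emission_t = stim.onset + stim.cutoff
    for t, v in zip(trace.times, trace.values):
        out = detector.push(float(t), float(v))
        if out is not None:
            result = out
            emission_t = t
            break
    if result is None:
        result = detector.finalize()
    if result.detected:
        stim_duration = float(min(emission_t - stim.onset, stim.cutoff))
        return TrialRecord(
            outcome="detected",
            latency_ms=result.latency,
            censored=False,
            threshold_mN=math.nan,
            stim_duration_ms=stim_duration,
            aim_time_ms=aim.time_ms,
            true_latency_ms=truth,
            **base,
        )
    return TrialRecord(
        outcome="censored",
        latency_ms=result.censor_time,
        censored=True,
        threshold_mN=math.nan,
        stim_duration_ms=stim.cutoff,
        aim_time_ms=aim.time_ms,
        true_latency_ms=truth,
        **base,
    )


def run_session(
    plan: SessionPlan,
    rigs: dict[str, VirtualRig],
    stim: StimulusEvent,
    cfg: ControllerConfig = ControllerConfig(),
    det: DetectionConfig = DetectionConfig(),
    epoch: str = "2023-01-01T00:00:00",
) -> list[TrialRecord]:
    """Run an interleaved, randomized multi-mouse session.

    A virtual wall clock advances as trials run (aiming time + stimulus
    duration + a 5 s handling allowance for moving between stations).  No
    mouse is re-stimulated before its inter-stimulus interval has elapsed
    since its previous stimulus onset; when the schedule would violate
    that, the clock waits.  The per-round order is a seeded permutation of
    the mouse IDs when ``randomize`` is set.
    """
    import datetime as _dt

    missing = [m for m in plan.mouse_ids if m not in rigs]
    if missing:
        raise ValueError(f"no rig for mice {missing}")
    if cfg.giveup_period < cfg.settle_period:
        warnings.warn(
            "give-up period shorter than settle period: no trial can ever stimulate",
            stacklevel=2,
        )
    rng = np.random.default_rng(plan.seed)
    t0 = _dt.datetime.fromisoformat(epoch)
    now = 0.0  # virtual seconds
    last_onset: dict[str, float] = {}
    records: list[TrialRecord] = []
    handling_s = 5.0
    for rnd in range(plan.trials_per_mouse):
        order = list(plan.mouse_ids)
        if plan.randomize:
            order = [order[i] for i in rng.permutation(len(order))]
        for idx, mouse in enumerate(order):
            earliest = last_onset.get(mouse, -math.inf) + plan.interval
            start = max(now, earliest)
            stamp = (t0 + _dt.timedelta(seconds=start)).isoformat()
            trial_seed = int(
                (plan.seed * 1009 + rnd * 131 + zlib.crc32(mouse.encode()) % 1000) % (2**31)
            )
            rec = run_trial(
                rigs[mouse], stim, cfg, det, seed=trial_seed, timestamp=stamp
            )
            records.append(rec)
            if rec.outcome != "skipped":
                onset_s = start + rec.aim_time_ms / 1000.0
                last_onset[mouse] = onset_s
                now = onset_s + rec.stim_duration_ms / 1000.0 + handling_s
            else:
                now = start + rec.aim_time_ms / 1000.0 + handling_s
    return records
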