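"""Signal-domain types and withdrawal detectors.

A withdrawal (the nocifensive reflex of a mouse pulling its hind paw away
from a noxious stimulus) is detected from one of three 1 kHz signals:

* **reflectance** (mV) — red light reflected off the paw, measured by a
  photodetector under the platform.  Withdrawal removes the paw from the
  beam and the reflectance drops.
* **paw height** (px) — vertical paw position tracked from high-speed
  video.  Withdrawal lifts the paw.
* **force** (mN) — load measured by a force-feedback indenter pressed
  against the paw through a grate floor.  Withdrawal unloads the indenter
  abruptly.

All three detectors share the same structure: establish a pre-stimulus
baseline, then find the first post-onset sample at which the signal crosses
a threshold defined relative to that baseline.  The reflectance detector
additionally requires the signal to stay below threshold for longer than a
persistence period before the crossing qualifies; the reported latency is
the time of the *start* of that period, not the time the persistence
criterion is finally met.

A streaming (push one sample at a time) variant of the reflectance detector
is provided for closed-loop use: the stimulus can be terminated the moment
the persistence criterion is satisfied.  It is contractually equivalent to
the offline detector on the same samples.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "VALID_UNITS",
    "UnitError",
    "SignalTrace",
    "StimulusEvent",
    "DetectionConfig",
    "WithdrawalResult",
    "ForceResult",
    "smooth_running_average",
    "baseline_level",
    "detect_withdrawal_reflectance",
    "detect_withdrawal_height",
    "detect_withdrawal_force",
    "StreamingWithdrawalDetector",
]

#: physical units a trace may carry (reflectance, force, pixel height,
#: delivered optical power)
VALID_UNITS = ("mV", "mN", "px", "mW")

MODALITIES = ("optogenetic", "thermal", "mechanical")
WAVEFORMS = ("pulse", "ramp", "custom")


class UnitError(ValueError):
    """A trace carries the wrong physical unit for the requested operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled time series with physical units.

    Sample ``k`` maps to time ``t0 + k * (1000 / fs)`` ms.

    Parameters
    ----------
    values : array-like
        Ordered real samples (length >= 1, all finite).
    fs : float
        Sampling rate in Hz (default 1000, the rig's acquisition rate).
    t0 : float
        Time of the first sample in ms.
    units : str
        One of :data:`VALID_UNITS`.
    """

    values: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace values must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        if self.units not in VALID_UNITS:
            raise UnitError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        object.__setattr__(self, "values", vals)

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.values.size) * self.dt

    @property
    def t_end(self) -> float:
        """Time of the last sample in ms."""
        return self.t0 + (self.values.size - 1) * self.dt

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: modality, waveform, onset time, intensity and cutoff.

    ``intensity`` is in mW for optogenetic pulses, mN/s for mechanical
    ramps (the ramp rate), and arbitrary laser-power units for thermal
    stimuli.  ``cutoff`` is the maximum stimulus duration in ms; a trial
    with no detected withdrawal by then is censored.  ``wavelength_nm``
    is metadata (455 blue / 625 red / 980 IR on the physical rig).
    """

    modality: str
    waveform: str = "pulse"
    onset: float = 0.0
    intensity: float = 0.0
    cutoff: float = 20000.0
    wavelength_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not (self.cutoff > 0):
            raise ValueError("cutoff must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class DetectionConfig:
    """Detector parameters (all durations in ms).

    Defaults are the rig's operating values: 0.5 s pre-stimulus baseline,
    27 ms running-average smoothing, a 2 mV reflectance drop held for
    longer than 20 ms, a 6 px height rise, and — for the mechanical
    channel — a fall to <= 50 % of the running peak force within 50 ms.
    ``force_min_peak`` guards the mechanical drop rule against firing
    while the indenter force is still near zero early in the ramp.
    """

    baseline_window: float = 500.0
    smooth_window: float = 27.0
    reflectance_drop: float = 2.0
    persistence: float = 20.0
    height_rise: float = 6.0
    force_drop_fraction: float = 0.5
    force_drop_window: float = 50.0
    force_min_peak: float = 5.0
    smooth_height: bool = False

    def __post_init__(self) -> None:
        for name in (
            "baseline_window",
            "smooth_window",
            "reflectance_drop",
            "persistence",
            "height_rise",
            "force_drop_window",
            "force_min_peak",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if not (0 < self.force_drop_fraction <= 1):
            raise ValueError("force_drop_fraction must be in (0, 1]")

    def smooth_samples(self, fs: float) -> int:
        """Realized smoothing-window width in samples at rate ``fs``."""
        return max(1, round(self.smooth_window * fs / 1000.0))


@dataclass(frozen=True)
class WithdrawalResult:
    """Outcome of withdrawal detection on one trial.

    A censored trial (no detection before the cutoff) reports
    ``latency == censor_time`` with ``censored=True`` so that downstream
    tables stay rectangular.
    """

    detected: bool
    latency: float
    censored: bool
    censor_time: float
    channel: str
    smooth_samples: int = 0

    def __post_init__(self) -> None:
        if self.detected and not (0 < self.latency <= self.censor_time):
            raise ValueError("detected withdrawal requires 0 < latency <= censor_time")
        if self.detected and self.censored:
            raise ValueError("a detected trial cannot be censored")


@dataclass(frozen=True)
class ForceResult(WithdrawalResult):
    """Withdrawal result for the mechanical channel.

    ``threshold_force`` is the peak force (mN) immediately preceding the
    withdrawal — the mechanical withdrawal threshold.  NaN when censored.
    """

    threshold_force: float = float("nan")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.detected and not (self.threshold_force > 0):
            raise ValueError("detected mechanical withdrawal requires threshold_force > 0")


# ---------------------------------------------------------------------------
# offline operations
# ---------------------------------------------------------------------------


def smooth_running_average(trace: SignalTrace, window: float) -> SignalTrace:
    """Trailing (causal) running average over ``window`` ms.

    Sample ``k`` of the result is the mean of the trailing window ending at
    ``k``.  The window is truncated at the start of the trace, so the first
    output sample equals the first raw sample.  The causal alignment is what
    makes the offline and streaming detectors equivalent.
    """
    n = max(1, round(window * trace.fs / 1000.0))
    if n > len(trace):
        raise ValueError("window exceeds trace")
    c = np.cumsum(trace.values)
    out = np.empty_like(trace.values)
    head = min(n, len(trace))
    out[:head] = c[:head] / np.arange(1, head + 1)
    if len(trace) > n:
        out[n:] = (c[n:] - c[:-n]) / n
    return replace(trace, values=out)


def _window_slice(times: np.ndarray, lo: float, hi: float) -> slice:
    """Indices of samples with time in [lo, hi)."""
    i0 = int(np.searchsorted(times, lo, side="left"))
    i1 = int(np.searchsorted(times, hi, side="left"))
    return slice(i0, i1)


def baseline_level(trace: SignalTrace, onset: float, window: float) -> float:
    """Mean of the samples in ``[onset - window, onset)``.

    This is the pre-stimulus baseline: by convention 0.5 s ending at
    stimulus onset, with the onset sample itself excluded.
    """
    if onset - window < trace.t0 - 1e-9:
        raise ValueError("baseline window not covered")
    sl = _window_slice(trace.times, onset - window, onset)
    if sl.stop <= sl.start:
        raise ValueError("baseline window not covered")
    return float(np.mean(trace.values[sl]))


def _first_persistent_run(below: np.ndarray, dt: float, persistence: float) -> Optional[int]:
    """Start index of the first True run lasting strictly longer than
    ``persistence`` ms (run duration counted as ``n_samples * dt``), or None.
    """
    if below.size == 0:
        return None
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.astype(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]
    for s, e in zip(starts, stops):
        if (e - s) * dt > persistence:
            return int(s)
    return None


def _require_coverage(trace: SignalTrace, stim: StimulusEvent, pre: float) -> None:
    if trace.t0 > stim.onset - pre + 1e-9:
        raise ValueError("trace does not cover the pre-stimulus baseline window")
    if trace.t_end < stim.onset + stim.cutoff - 1e-9:
        raise ValueError("trace does not cover the stimulus epoch up to cutoff")


def detect_withdrawal_reflectance(
    trace: SignalTrace, stim: StimulusEvent, cfg: DetectionConfig = DetectionConfig()
) -> WithdrawalResult:
    """Detect withdrawal from the red-reflectance signal.

    The trace is smoothed with the trailing running average, the baseline is
    taken over the pre-stimulus window, and the withdrawal is the first
    post-onset sample at which the smoothed signal falls strictly below
    ``baseline - reflectance_drop`` *and* the sub-threshold run lasts
    strictly longer than ``persistence`` ms.  Latency is measured from
    stimulus onset to the start of that run.  If no qualifying run occurs
    before the cutoff the trial is censored.
    """
    if trace.units != "mV":
        raise UnitError(f"reflectance detector expects mV, got {trace.units}")
    _require_coverage(trace, stim, cfg.baseline_window)
    sm = smooth_running_average(trace, cfg.smooth_window)
    base = baseline_level(sm, stim.onset, cfg.baseline_window)
    threshold = base - cfg.reflectance_drop
    times = sm.times
    i0 = int(np.searchsorted(times, stim.onset, side="right"))
    i1 = int(np.searchsorted(times, stim.onset + stim.cutoff, side="right"))
    below = sm.values[i0:i1] < threshold
    start = _first_persistent_run(below, sm.dt, cfg.persistence)
    nsm = cfg.smooth_samples(trace.fs)
    if start is None:
        return WithdrawalResult(False, stim.cutoff, True, stim.cutoff, "reflectance", nsm)
    latency = float(times[i0 + start] - stim.onset)
    return WithdrawalResult(True, latency, False, stim.cutoff, "reflectance", nsm)


def detect_withdrawal_height(
    traj: SignalTrace, stim: StimulusEvent, cfg: DetectionConfig = DetectionConfig()
) -> WithdrawalResult:
    """Detect withdrawal from the tracked paw-height trajectory (px).

    Latency is the first post-onset time at which height rises strictly more
    than ``height_rise`` px above the pre-stimulus baseline.  No smoothing
    is applied by default (set ``cfg.smooth_height`` to smooth with the same
    trailing window as the reflectance channel) and no persistence rule is
    applied: only a rise counts, a paw pressed down never triggers.
    """
    if traj.units != "px":
        raise UnitError(f"height detector expects px, got {traj.units}")
    _require_coverage(traj, stim, cfg.baseline_window)
    sig = smooth_running_average(traj, cfg.smooth_window) if cfg.smooth_height else traj
    base = baseline_level(sig, stim.onset, cfg.baseline_window)
    times = sig.times
    i0 = int(np.searchsorted(times, stim.onset, side="right"))
    i1 = int(np.searchsorted(times, stim.onset + stim.cutoff, side="right"))
    above = np.flatnonzero(sig.values[i0:i1] > base + cfg.height_rise)
    nsm = cfg.smooth_samples(traj.fs) if cfg.smooth_height else 0
    if above.size == 0:
        return WithdrawalResult(False, stim.cutoff, True, stim.cutoff, "height", nsm)
    latency = float(times[i0 + int(above[0])] - stim.onset)
    return WithdrawalResult(True, latency, False, stim.cutoff, "height", nsm)


def detect_withdrawal_force(
    force: SignalTrace, stim: StimulusEvent, cfg: DetectionConfig = DetectionConfig()
) -> ForceResult:
    """Detect withdrawal from the indenter force signal during a ramp.

    Withdrawal unloads the indenter abruptly.  The rule: smooth the force
    with the trailing running average and flag the first sample at which the
    smoothed force falls strictly below ``force_drop_fraction`` times its
    rolling maximum over the trailing ``force_drop_window`` ms — i.e. a
    loss of more than half the load within 50 ms at the defaults.  The
    mechanical threshold is the raw running-peak force at that moment.  To
    avoid spurious triggers while the ramp force is still within the noise
    floor, detection requires the raw running peak to have reached
    ``force_min_peak`` first.
    """
    if force.units != "mN":
        raise UnitError(f"force detector expects mN, got {force.units}")
    if force.t0 > stim.onset + 1e-9:
        raise ValueError("trace does not cover stimulus onset")
    if force.t_end < stim.onset + stim.cutoff - 1e-9:
        raise ValueError("trace does not cover the stimulus epoch up to cutoff")
    sm = smooth_running_average(force, cfg.smooth_window)
    times = force.times
    i0 = int(np.searchsorted(times, stim.onset, side="right"))
    i1 = int(np.searchsorted(times, stim.onset + stim.cutoff, side="right"))
    raw = force.values[i0:i1]
    smo = sm.values[i0:i1]
    nsm = cfg.smooth_samples(force.fs)
    if raw.size == 0 or not np.any(raw > 0):
        return ForceResult(False, stim.cutoff, True, stim.cutoff, "force", nsm)
    running_peak = np.maximum.accumulate(raw)
    nw = max(1, round(cfg.force_drop_window * force.fs / 1000.0))
    # trailing rolling max of the smoothed force
    roll_max = pd.Series(smo).rolling(nw, min_periods=1).max().to_numpy()
    hit = np.flatnonzero(
        (smo < cfg.force_drop_fraction * roll_max) & (running_peak >= cfg.force_min_peak)
    )
    if hit.size == 0:
        return ForceResult(False, stim.cutoff, True, stim.cutoff, "force", nsm)
    k = int(hit[0])
    latency = float(times[i0 + k] - stim.onset)
    return ForceResult(
        True, latency, False, stim.cutoff, "force", nsm, threshold_force=float(running_peak[k])
    )


# ---------------------------------------------------------------------------
# streaming detector
# ---------------------------------------------------------------------------


class StreamingWithdrawalDetector:
    """Push-based reflectance detector for closed-loop stimulus control.

    Samples are pushed in time order at the trace sampling rate.  The
    detector maintains the trailing-window mean and the sub-threshold run
    length incrementally, and emits a :class:`WithdrawalResult` the moment
    the persistence criterion is satisfied (the *emission* is delayed by
    the persistence duration; the reported latency refers to the start of
    the sub-threshold run, exactly as in the offline detector).  Replaying
    any trace yields the same (detected, latency, censored) as
    :func:`detect_withdrawal_reflectance`.

    Parameters
    ----------
    stim : StimulusEvent
    cfg : DetectionConfig
    fs : float
        Sampling rate in Hz of the incoming stream.
    """

    def __init__(
        self, stim: StimulusEvent, cfg: DetectionConfig = DetectionConfig(), fs: float = 1000.0
    ) -> None:
        self.stim = stim
        self.cfg = cfg
        self.fs = fs
        self.dt = 1000.0 / fs
        self.n_smooth = cfg.smooth_samples(fs)
        self._win: deque = deque(maxlen=self.n_smooth)
        self._wsum = 0.0
        self._base_sum = 0.0
        self._base_n = 0
        self._threshold: Optional[float] = None
        self._run_start: Optional[float] = None
        self._run_len = 0
        self._last_t: Optional[float] = None
        self.result: Optional[WithdrawalResult] = None

    def _smoothed(self, v: float) -> float:
        if len(self._win) == self.n_smooth:
            self._wsum -= self._win[0]
        self._win.append(v)
        self._wsum += v
        return self._wsum / len(self._win)

    def push(self, t: float, v: float) -> Optional[WithdrawalResult]:
        """Push one sample; return a result the moment one is decided."""
        if self._last_t is not None and t <= self._last_t:
            raise ValueError("out-of-order sample")
        self._last_t = t
        sm = self._smoothed(v)
        onset = self.stim.onset
        if t < onset:
            if t >= onset - self.cfg.baseline_window:
                self._base_sum += sm
                self._base_n += 1
            return None
        if self._threshold is None:
            if self._base_n == 0:
                raise ValueError("baseline window not covered")
            self._threshold = self._base_sum / self._base_n - self.cfg.reflectance_drop
        if self.result is not None:
            return None
        if t > onset + self.stim.cutoff:
            self.result = WithdrawalResult(
                False, self.stim.cutoff, True, self.stim.cutoff, "reflectance", self.n_smooth
            )
            return self.result
        if t <= onset:  # the onset sample belongs to neither baseline nor response
            return None
        if sm < self._threshold:
            if self._run_len == 0:
                self._run_start = t
            self._run_len += 1
            if self._run_len * self.dt > self.cfg.persistence:
                latency = self._run_start - onset
                self.result = WithdrawalResult(
                    True, latency, False, self.stim.cutoff, "reflectance", self.n_smooth
                )
                return self.result
        else:
            self._run_len = 0
            self._run_start = None
        return None

    def finalize(self) -> WithdrawalResult:
        """Close the stream; a stream with no decision is censored."""
        if self.result is None:
            self.result = WithdrawalResult(
                False, self.stim.cutoff, True, self.stim.cutoff, "reflectance", self.n_smooth
            )
        return self.result

    def replay(self, trace: SignalTrace) -> WithdrawalResult:
        """Convenience: push a whole trace sample-by-sample and finalize."""
        if trace.units != "mV":
            raise UnitError(f"reflectance detector expects mV, got {trace.units}")
        for t, v in zip(trace.times, trace.values):
            out = self.push(float(t), float(v))
            if out is not None:
                return out
        return self.finalize()
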