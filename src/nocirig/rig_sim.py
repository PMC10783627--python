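"""Virtual stimulation rig with known ground truth.

The physical rig directs a focused light beam (blue for optogenetic
activation, IR for radiant heating, red for aiming/withdrawal measurement)
upward through a clear platform onto a mouse hind paw, with a substage
camera for aiming.  This module models the parts of that system needed to
exercise the detection, control and analysis code against known ground
truth:

* beam geometry — a straight-edge divergence cone parameterized by the
  focal-plane spot diameter and the fiber numerical aperture, and the
  on-target power as the geometric overlap of the beam disc with a
  paw-shaped aperture;
* tester jitter — per-sample beam displacement models contrasting a
  handheld fiber optic with a rigidly mounted stimulator;
* a virtual paw — reflectance, force and paw-height trace generators with
  a programmed true withdrawal latency;
* key-point streams — 30 fps coordinates for the tracked body parts with
  pixel noise calibrated to pose-estimation test error, driving the aiming
  controller.

All generators are deterministic functions of their parameters and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

from .signals import SignalTrace, StimulusEvent

__all__ = [
    "BeamModel",
    "PawAperture",
    "JitterModel",
    "VirtualPaw",
    "KeyPointStream",
    "VirtualRig",
    "KEYPOINT_PARTS",
    "beam_radius_at",
    "on_target_power",
    "simulate_power_trace",
    "simulate_reflectance_trial",
    "simulate_force_trial",
    "simulate_keypoints",
]

#: body parts the pose network reports, substage (bottom-up) view
KEYPOINT_PARTS = (
    "snout",
    "left_fore",
    "right_fore",
    "left_hind",
    "right_hind",
    "tail_base",
)

#: the stimulated paw, tracked for aiming
TARGET_PART = "left_hind"


# ---------------------------------------------------------------------------
# beam geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamModel:
    """Light beam at the platform.

    ``spot_diameter`` is the focal-plane spot diameter in mm (5 mm on the
    rig, i.e. a ~20 mm^2 spot); ``numerical_aperture`` sets the divergence
    half-angle ``asin(NA)`` of rays beyond the focal plane; ``total_power``
    is the delivered optical power in mW.
    """

    spot_diameter: float = 5.0
    numerical_aperture: float = 0.48
    total_power: float = 20.0
    profile: str = "uniform_disc"

    def __post_init__(self) -> None:
        if not (self.spot_diameter > 0):
            raise ValueError("spot_diameter must be positive")
        if not (0 < self.numerical_aperture < 1):
            raise ValueError("numerical aperture must be in (0, 1)")
        if self.total_power < 0:
            raise ValueError("total_power must be non-negative")
        if self.profile not in ("uniform_disc", "gaussian"):
            raise ValueError(f"unknown beam profile {self.profile!r}")

    @property
    def spot_area(self) -> float:
        """Focal-plane spot area in mm^2 (power / area = irradiance)."""
        return math.pi * (self.spot_diameter / 2.0) ** 2


@dataclass(frozen=True)
class PawAperture:
    """Paw-shaped target region on the platform, modeled as an ellipse.

    Defaults approximate a mouse hind-paw footprint: 10 mm along the long
    (x) axis by 4 mm across.
    """

    length: float = 10.0
    width: float = 4.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("aperture axes must be positive")

    @property
    def polygon(self) -> Polygon:
        circ = Point(0.0, 0.0).buffer(1.0, quad_segs=96)
        ell = shapely.affinity.scale(circ, self.length / 2.0, self.width / 2.0)
        return shapely.affinity.translate(ell, *self.center)


@dataclass(frozen=True)
class JitterModel:
    """Per-sample displacement of the beam axis relative to the target.

    ``gaussian_iid`` draws an independent offset each sample (hand tremor
    at coarse time scales); ``random_walk`` integrates Gaussian steps
    (slow drift of a handheld fiber).  ``none`` is the rigidly mounted
    stimulator.
    """

    kind: str = "none"
    sd_xy: float = 0.0
    sd_z: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_iid", "random_walk"):
            raise ValueError(f"unknown jitter kind {self.kind!r}")
        if self.sd_xy < 0 or self.sd_z < 0:
            raise ValueError("jitter sd must be non-negative")
        if self.kind == "none" and (self.sd_xy != 0 or self.sd_z != 0):
            raise ValueError("kind='none' requires zero sds")

    def offsets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, 3) array of per-sample (x, y, z) offsets in mm."""
        if self.kind == "none":
            return np.zeros((n, 3))
        steps = rng.normal(0.0, [self.sd_xy, self.sd_xy, self.sd_z], size=(n, 3))
        if self.kind == "random_walk":
            steps = np.cumsum(steps, axis=0)
        steps[:, 2] = np.abs(steps[:, 2])  # z measured beyond focus, >= 0
        return steps


def beam_radius_at(beam: BeamModel, z: float) -> float:
    """Beam radius (mm) at distance ``z`` mm beyond the focal plane.

    Straight-edge cone: ``r(z) = spot_diameter/2 + z * tan(asin(NA))``.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if not (beam.numerical_aperture < 1):
        raise ValueError("numerical aperture must be < 1")
    half_angle = math.asin(beam.numerical_aperture)
    return beam.spot_diameter / 2.0 + z * math.tan(half_angle)


def on_target_power(
    beam: BeamModel,
    aperture: PawAperture,
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> float:
    """Optical power (mW) landing inside the aperture.

    For the uniform-disc profile this is ``total_power`` times the area
    fraction of the beam disc (radius set by ``z``) overlapping the
    aperture.  For the Gaussian profile the irradiance (1/e^2 radius equal
    to the disc radius) is integrated over the aperture on a grid.
    Disjoint geometry yields 0.
    """
    x, y, z = offset
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise ValueError("offsets must be finite")
    r = beam_radius_at(beam, z)
    ap = aperture.polygon
    if beam.profile == "uniform_disc":
        disc = Point(x, y).buffer(r, quad_segs=96)
        frac = disc.intersection(ap).area / disc.area
        return beam.total_power * frac
    # gaussian: integrate 2D isotropic Gaussian (sigma = r/2) over the aperture
    sigma = r / 2.0
    minx, miny, maxx, maxy = ap.bounds
    n = 121
    gx = np.linspace(minx, maxx, n)
    gy = np.linspace(miny, maxy, n)
    xx, yy = np.meshgrid(gx, gy)
    inside = shapely.contains_xy(ap, xx.ravel(), yy.ravel()).reshape(xx.shape)
    dens = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))) / (2 * math.pi * sigma**2)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    frac = float(np.sum(dens * inside) * cell)
    return beam.total_power * min(frac, 1.0)


def simulate_power_trace(
    beam: BeamModel,
    aperture: PawAperture,
    jitter: JitterModel,
    duration: float,
    fs: float = 100.0,
    seed: int = 0,
    base_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SignalTrace:
    """On-target power vs. time under beam jitter.

    Each sample draws an offset from the jitter model (added to
    ``base_offset``) and evaluates :func:`on_target_power`.  Deterministic
    for a fixed seed.  ``fs`` defaults to 100 Hz — beam wander is slow
    relative to the 1 kHz acquisition channels and the overlap integral
    dominates the cost.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    n = max(1, round(duration * fs / 1000.0))
    rng = np.random.default_rng(seed)
    offs = jitter.offsets(n, rng)
    bx, by, bz = base_offset
    vals = np.empty(n)
    for k in range(n):
        vals[k] = on_target_power(
            beam, aperture, (bx + offs[k, 0], by + offs[k, 1], max(0.0, bz + offs[k, 2]))
        )
    return SignalTrace(vals, fs=fs, t0=0.0, units="mW")


# ---------------------------------------------------------------------------
# virtual paw
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VirtualPaw:
    """Ground-truth withdrawal kinematics and reflectance statistics.

    ``true_latency`` is the programmed time (ms after stimulus onset) at
    which the paw leaves the beam; the reflectance then falls by
    ``reflectance_drop`` mV linearly over ``transition_ms`` (default 10 ms,
    the time a ~2 px/ms withdrawal takes to clear the 5 mm spot at typical
    substage magnification).  ``drift`` models slow baseline wander in
    mV/s; ``noise_sd`` is per-sample Gaussian noise in mV.
    """

    true_latency: float = 150.0
    withdrawal_speed: float = 2.0
    reflectance_baseline: float = 100.0
    reflectance_drop: float = 5.0
    noise_sd: float = 0.3
    drift: float = 0.0
    transition_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.true_latency > 0):
            raise ValueError("true_latency must be positive")
        if not (self.reflectance_drop > 0):
            raise ValueError("reflectance_drop must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_reflectance_trial(
    paw: VirtualPaw,
    stim: StimulusEvent,
    fs: float = 1000.0,
    pre_window: float = 500.0,
) -> tuple[SignalTrace, float]:
    """Reflectance trace for one trial, plus the ground-truth latency.

    The trace starts ``pre_window`` ms before stimulus onset and ends at
    ``onset + cutoff``.  Reflectance sits at baseline (+ drift + noise)
    until ``onset + true_latency``, then falls by ``reflectance_drop``
    linearly over ``transition_ms`` and stays down.  A true latency beyond
    the cutoff leaves the trace flat (a censored trial).
    """
    t0 = stim.onset - pre_window
    n = round((pre_window + stim.cutoff) * fs / 1000.0) + 1
    dt = 1000.0 / fs
    t = t0 + np.arange(n) * dt
    rng = np.random.default_rng(paw.seed)
    vals = (
        paw.reflectance_baseline
        + paw.drift * (t - t0) / 1000.0
        + rng.normal(0.0, paw.noise_sd, size=n)
    )
    t_w = stim.onset + paw.true_latency
    ramp = np.clip((t - t_w) / paw.transition_ms, 0.0, 1.0)
    vals -= paw.reflectance_drop * ramp
    return SignalTrace(vals, fs=fs, t0=t0, units="mV"), paw.true_latency


def simulate_force_trial(
    withdrawal_force: float,
    ramp_rate: float,
    noise_sd: float = 0.0,
    fs: float = 1000.0,
    seed: int = 0,
    cutoff: float = 20000.0,
    collapse_ms: float = 5.0,
) -> tuple[SignalTrace, tuple[float, float]]:
    """Indenter force trace for one mechanical ramp trial.

    Force rises at ``ramp_rate`` mN/s from stimulus onset (t = 0) until it
    reaches ``withdrawal_force`` mN, then collapses to ~0 within
    ``collapse_ms`` (the abrupt unloading of withdrawal).  If the
    withdrawal force would only be reached after the cutoff, the ramp
    simply continues to the cutoff (a censored trial).  Returns the trace
    and the ground truth ``(latency_ms, threshold_mN)``.
    """
    if not (ramp_rate > 0):
        raise ValueError("ramp_rate must be positive")
    if not (withdrawal_force > 0):
        raise ValueError("withdrawal_force must be positive")
    dt = 1000.0 / fs
    n = round(cutoff / dt) + 1
    t = np.arange(n) * dt
    t_w = withdrawal_force / ramp_rate * 1000.0  # ms
    ramp = ramp_rate * t / 1000.0
    if t_w <= cutoff:
        after = np.clip((t - t_w) / collapse_ms, 0.0, 1.0)
        vals = np.where(t <= t_w, ramp, withdrawal_force * (1.0 - after))
    else:
        vals = ramp
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=n)
    truth = (t_w, withdrawal_force)
    return SignalTrace(vals, fs=fs, t0=0.0, units="mN"), truth


# ---------------------------------------------------------------------------
# key-point streams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeyPointStream:
    """Per-frame body-part coordinates with confidence, image convention.

    ``table`` is long format with columns (frame, time_ms, part, x_px,
    y_px, confidence); origin at the top-left of the arena, x right,
    y down.  The default arena is a 640x480 frame whose center (320, 240)
    is the stimulation crosshair.
    """

    table: pd.DataFrame
    fps: float = 30.0
    arena: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        required = {"frame", "time_ms", "part", "x_px", "y_px", "confidence"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"key-point table must have columns {sorted(required)}")

    @property
    def n_frames(self) -> int:
        return int(self.table["frame"].nunique())

    @property
    def frame_interval(self) -> float:
        """Frame duration in ms."""
        return 1000.0 / self.fps

    def part_track(self, part: str) -> pd.DataFrame:
        """Frames for one body part, ordered, indexed by frame."""
        sub = self.table[self.table["part"] == part]
        if sub.empty:
            raise KeyError(f"no such part {part!r}")
        return sub.sort_values("frame").reset_index(drop=True)


#: nominal offsets (px) of non-target parts from the body center, bottom-up view
_BODY_PLAN = {
    "snout": (60.0, 0.0),
    "left_fore": (30.0, -20.0),
    "right_fore": (30.0, 20.0),
    "left_hind": (-25.0, -25.0),
    "right_hind": (-25.0, 25.0),
    "tail_base": (-60.0, 0.0),
}


def simulate_keypoints(
    motion: str = "stationary_bouts",
    duration: float = 10000.0,
    fps: float = 30.0,
    noise_px: float = 3.33,
    seed: int = 0,
    bout_duration: float = 4000.0,
    step_px: float = 2.0,
    arena: tuple[int, int] = (640, 480),
    start: Optional[tuple[float, float]] = None,
    low_conf_prob: float = 0.0,
) -> KeyPointStream:
    """Simulated pose-estimation stream for one mouse.

    ``stationary_bouts``: the body (and with it the target hind paw) sits
    still for ``bout_duration`` ms, then relocates instantly to a new
    uniform position within the arena margins — the stop-and-go statistics
    an aiming controller must cope with.  ``random_walk``: the body takes
    a Gaussian step of scale ``step_px`` every frame.  Per-frame
    coordinate noise with SD ``noise_px`` models pose-estimation error
    (default 3.33 px, the target hind-paw test error of the tracking
    network).  Each frame's confidence is ~0.95, degraded below 0.5 with
    probability ``low_conf_prob`` to model frames where the paw is not
    recognized.  Deterministic for a fixed seed.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    if motion not in ("stationary_bouts", "random_walk"):
        raise ValueError(f"unknown motion model {motion!r}")
    rng = np.random.default_rng(seed)
    n = max(1, round(duration * fps / 1000.0))
    w, h = arena
    margin = 80.0
    if start is None:
        center0 = np.array(
            [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
        )
    else:
        center0 = np.asarray(start, dtype=float)
    centers = np.empty((n, 2))
    if motion == "stationary_bouts":
        frames_per_bout = max(1, round(bout_duration * fps / 1000.0))
        pos = center0.copy()
        for k in range(n):
            if k > 0 and k % frames_per_bout == 0:
                pos = np.array(
                    [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
                )
            centers[k] = pos
    else:
        steps = rng.normal(0.0, step_px, size=(n, 2))
        steps[0] = 0.0
        centers = center0 + np.cumsum(steps, axis=0)
        centers[:, 0] = np.clip(centers[:, 0], margin, w - margin)
        centers[:, 1] = np.clip(centers[:, 1], margin, h - margin)

    frames = np.arange(n)
    time_ms = frames * (1000.0 / fps)
    rows = []
    for part in KEYPOINT_PARTS:
        off = np.asarray(_BODY_PLAN[part])
        xy = centers + off + rng.normal(0.0, noise_px, size=(n, 2))
        conf = np.full(n, 0.95)
        if low_conf_prob > 0:
            lost = rng.random(n) < low_conf_prob
            conf[lost] = 0.1
        rows.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "time_ms": time_ms,
                    "part": part,
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "confidence": conf,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return KeyPointStream(table=table, fps=fps, arena=arena)


# ---------------------------------------------------------------------------
# whole-rig bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VirtualRig:
    """One virtual testing station: beam, aperture, jitter, paw, motion.

    The ground-truth generator behind a full simulated trial: the
    controller aims at the key-point stream, the stimulus fires, and the
    paw emits a reflectance trace with the programmed latency.
    """

    paw: VirtualPaw = field(default_factory=VirtualPaw)
    beam: BeamModel = field(default_factory=BeamModel)
    aperture: PawAperture = field(default_factory=PawAperture)
    jitter: JitterModel = field(default_factory=JitterModel)
    mouse_id: str = "m01"
    fs: float = 1000.0
    fps: float = 30.0
    motion: str = "stationary_bouts"
    bout_duration: float = 6000.0
    keypoint_noise_px: float = 1.0
    seed: int = 0

    def keypoint_stream(self, duration: float, seed: Optional[int] = None) -> KeyPointStream:
        return simulate_keypoints(
            motion=self.motion,
            duration=duration,
            fps=self.fps,
            noise_px=self.keypoint_noise_px,
            seed=self.seed if seed is None else seed,
            bout_duration=self.bout_duration,
        )

    def reflectance_trial(
        self, stim: StimulusEvent, seed: Optional[int] = None
    ) -> tuple[SignalTrace, float]:
        paw = self.paw if seed is None else dataclasses.replace(self.paw, seed=seed)
        return simulate_reflectance_trial(paw, stim, fs=self.fs)
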