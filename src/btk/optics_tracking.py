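"""Optics arithmetic and a closed-loop stage-tracking simulator.

Magnification for the two objective families used on the microscope:

* fixed-focal-length camera objectives: ``M = f_TL / f_OBJ``;
* infinity-corrected commercial objectives designed for a different tube
  lens: ``M_effective = (f_TL / f_design_TL) * M_nominal``.

The tracking simulator reproduces the stage-feedback loop: frames acquired
at the camera rate, an offset measured and a stage move commanded at the
update rate, commands taking effect after a communication latency, the
stage slewing at a capped speed, and frames acquired during stage motion
optionally skipped (blurred frames are useless for displacement
estimation).  Loss of the animal from the field of view is a result state,
not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DetectionError, ParameterError
from .synthetic_data import Trajectory

__all__ = [
    "OpticalConfig",
    "TrackerConfig",
    "TrackingResult",
    "magnification_fixed",
    "magnification_nominal",
    "detect_object_centroid",
    "simulate_closed_loop",
]


@dataclass(frozen=True)
class OpticalConfig:
    """One objective/tube-lens pairing."""

    f_TL: float  # mm, tube lens focal length
    f_OBJ: float | None = None  # mm, fixed-focal objective
    f_nominal_TL: float | None = None  # mm, the objective's design tube lens
    M_nominal: float | None = None

    @property
    def magnification(self) -> float:
        if self.f_OBJ is not None:
            return magnification_fixed(self.f_TL, self.f_OBJ)
        if self.f_nominal_TL is None or self.M_nominal is None:
            raise ParameterError("need either f_OBJ or (f_nominal_TL, M_nominal)")
        return magnification_nominal(self.f_TL, self.f_nominal_TL, self.M_nominal)


def magnification_fixed(f_TL: float, f_OBJ: float) -> float:
    """Magnification of a fixed-focal-length objective: ``f_TL / f_OBJ``."""
    if f_TL <= 0 or f_OBJ <= 0:
        raise ParameterError("focal lengths must be positive")
    return f_TL / f_OBJ


def magnification_nominal(f_TL: float, f_nominal_TL: float, M_nominal: float) -> float:
    """Effective magnification of a commercial objective on a non-design tube lens.

    ``M_effective = (f_TL / f_nominal_TL) * M_nominal`` — e.g. a 10x
    objective designed for a 180 mm tube lens used with a 50 mm tube lens
    gives 50/180 * 10 ≈ 2.78x.
    """
    if f_TL <= 0 or f_nominal_TL <= 0 or M_nominal <= 0:
        raise ParameterError("focal lengths and nominal magnification must be positive")
    return (f_TL / f_nominal_TL) * M_nominal


def detect_object_centroid(frame: np.ndarray, threshold: float) -> tuple[float, float]:
    """Intensity-weighted centroid of the largest above-threshold component.

    Returns (x, y) in pixel coordinates (x along columns, y along rows).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ParameterError("frame must be 2-D")
    above = frame > threshold
    if not above.any():
        raise DetectionError("no pixel above threshold")
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(frame), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    weights = frame * mask
    total = weights.sum()
    rows = np.arange(frame.shape[0])[:, None]
    cols = np.arange(frame.shape[1])[None, :]
    cy = float((weights * rows).sum() / total)
    cx = float((weights * cols).sum() / total)
    return cx, cy


@dataclass
class TrackerConfig:
    """Closed-loop tracker settings.

    Defaults mirror the real system: a 7.4 x 5.0 mm field of view at 1x, a
    20 mm/s stage speed cap, ~25 ms command latency, and skipping of frames
    acquired while the stage was moving.
    """

    fov_size: tuple[float, float] = (7.4, 5.0)  # mm (x, y)
    frame_rate: float = 30.0  # Hz
    update_rate: float = 10.0  # Hz
    stage_max_speed: float = 20.0  # mm/s
    command_latency: float = 0.025  # s
    detection_threshold: float = 0.0
    skip_during_motion: bool = True

    def __post_init__(self) -> None:
        if self.update_rate > self.frame_rate:
            raise ParameterError("update_rate must not exceed frame_rate")
        if self.stage_max_speed <= 0:
            raise ParameterError("stage_max_speed must be positive")


@dataclass
class TrackingResult:
    """Per-frame tracking record of one simulated run."""

    time: np.ndarray  # frame acquisition times, s
    offset: np.ndarray  # (n_frames, 2) true animal offset from FOV center, mm
    measured_offset: np.ndarray  # (n_frames, 2) offsets as seen by the tracker
    measured: np.ndarray  # frames where an offset was actually measured
    retained: bool
    loss_time: float | None
    effective_update_rate: float  # Hz, commands issued / duration

    @property
    def max_offset(self) -> float:
        return float(np.linalg.norm(self.offset, axis=1).max())


def simulate_closed_loop(trajectory: Trajectory, cfg: TrackerConfig) -> TrackingResult:
    """Run the stage-feedback loop against an animal trajectory.

    Discrete-event loop on the frame clock: at each frame the animal's
    offset from the FOV center is observed (unless the stage moved during
    the exposure and ``skip_during_motion`` is set, or the animal has left
    the FOV); at the update cadence a move command is issued, takes effect
    after ``command_latency``, and the stage slews toward the target at
    ``stage_max_speed``.  Only one command is in flight; a newer command
    replaces a pending one.  The run counts as retained while the offset
    never exceeds half the FOV diagonal.

    Frames exposed while the stage moves are motion-blurred: a centroid
    measured on such a frame is biased by half the stage displacement over
    the exposure (the centroid of a streak sits at its midpoint).  With
    ``skip_during_motion`` those frames are discarded instead — the
    tracker's rationale for ignoring frames acquired during stage motion.
    """
    dt = 1.0 / cfg.frame_rate
    n_frames = int(math.floor(trajectory.duration / dt)) + 1
    frame_times = trajectory.time[0] + np.arange(n_frames) * dt
    update_stride = max(int(round(cfg.frame_rate / cfg.update_rate)), 1)

    half_diag = 0.5 * math.hypot(*cfg.fov_size)
    half_x, half_y = cfg.fov_size[0] / 2.0, cfg.fov_size[1] / 2.0

    stage = np.array(trajectory.at(frame_times[0]), dtype=float)  # start centered
    target = stage.copy()
    pending: tuple[float, np.ndarray] | None = None  # (activation time, target)

    offsets = np.zeros((n_frames, 2))
    measured_offsets = np.full((n_frames, 2), np.nan)
    measured = np.zeros(n_frames, dtype=bool)
    retained = True
    loss_time: float | None = None
    n_commands = 0

    for i, t_frame in enumerate(frame_times):
        # advance the stage over the last frame interval in small steps so a
        # pending command can activate mid-interval
        stage_disp = np.zeros(2)
        if i > 0:
            t = t_frame - dt
            n_sub = 8
            sub = dt / n_sub
            for _ in range(n_sub):
                t += sub
                if pending is not None and t >= pending[0]:
                    target = pending[1]
                    pending = None
                delta = target - stage
                dist = float(np.linalg.norm(delta))
                if dist > 1e-12:
                    step = min(cfg.stage_max_speed * sub, dist)
                    move = delta / dist * step
                    stage += move
                    stage_disp += move
        moved_during_frame = bool(np.linalg.norm(stage_disp) > 1e-12)

        animal = np.asarray(trajectory.at(t_frame), dtype=float)
        off = animal - stage
        offsets[i] = off
        if retained and np.linalg.norm(off) > half_diag:
            retained = False
            loss_time = float(t_frame)

        visible = abs(off[0]) <= half_x and abs(off[1]) <= half_y
        skip = cfg.skip_during_motion and moved_during_frame
        if visible and not skip:
            # motion blur: the centroid of a streaked spot sits mid-streak
            seen = off + 0.5 * stage_disp if moved_during_frame else off
            measured_offsets[i] = seen
            measured[i] = True
            if i % update_stride == 0:
                pending = (t_frame + cfg.command_latency, stage + seen)
                n_commands += 1

    duration = frame_times[-1] - frame_times[0] if n_frames > 1 else dt
    return TrackingResult(
        time=frame_times,
        offset=offsets,
        measured_offset=measured_offsets,
        measured=measured,
        retained=retained,
        loss_time=loss_time,
        effective_update_rate=n_commands / duration,
    )
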