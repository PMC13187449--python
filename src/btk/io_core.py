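"""File formats and coordinate plumbing.

Reads and writes the formats the pipeline touches — pose tables in the
DeepLabCut three-header-row CSV dialect, stage-position logs, ethograms,
multi-page TIFF stacks, YAML configs — and merges camera-frame pose
coordinates with stage logs into a common laboratory frame (mm).

Conventions (stated once, used everywhere): pixel coordinates are 0-based
indices with x increasing rightward along image columns and y increasing
downward along image rows; the laboratory frame is in mm with the same axis
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import AlignmentError, FormatError, InputError

__all__ = [
    "PoseTrack",
    "StageLog",
    "ImageStack",
    "Ethogram",
    "read_pose_table",
    "write_pose_table",
    "read_stage_log",
    "write_stage_log",
    "read_ethogram",
    "write_ethogram",
    "read_stack",
    "write_stack",
    "load_config",
    "merge_with_stage",
]


@dataclass
class PoseTrack:
    """Per-frame labeled body-part coordinates with likelihoods.

    ``x``/``y``/``likelihood`` are ``(n_frames, n_parts)`` arrays ordered as
    in ``parts``.  ``units`` is ``"px"`` for raw camera coordinates or
    ``"mm"`` after merging with a stage log.
    """

    frame_index: np.ndarray
    time: np.ndarray
    parts: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    pixel_size: float  # µm/px
    units: str = "px"
    moving: np.ndarray | None = None  # set by merge_with_stage

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.parts = tuple(self.parts)
        n, p = len(self.frame_index), len(self.parts)
        for name in ("x", "y", "likelihood"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(n, p)
            setattr(self, name, arr)
        if len(self.time) != n:
            raise InputError("time and frame_index lengths differ")
        lk = self.likelihood[np.isfinite(self.likelihood)]
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise InputError("likelihoods must lie in [0, 1]")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise InputError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def part_xy(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.parts.index(part)
        return self.x[:, i], self.y[:, i]


@dataclass
class StageLog:
    """Timestamped stage positions in mm with a per-sample motion flag."""

    time: np.ndarray
    stage_x: np.ndarray
    stage_y: np.ndarray
    moving_flag: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stage_x = np.asarray(self.stage_x, dtype=float)
        self.stage_y = np.asarray(self.stage_y, dtype=float)
        self.moving_flag = np.asarray(self.moving_flag, dtype=bool)
        if not (len(self.time) == len(self.stage_x) == len(self.stage_y) == len(self.moving_flag)):
            raise InputError("stage log columns must have equal length")
        if np.any(np.diff(self.time) < 0):
            raise InputError("stage log time must be nondecreasing")
        if not (np.all(np.isfinite(self.stage_x)) and np.all(np.isfinite(self.stage_y))):
            raise InputError("stage coordinates must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ImageStack:
    """A (t, row, col) intensity stack with acquisition metadata.

    ``channel_layout`` is ``"single"`` for one channel per frame or
    ``"side-by-side"`` when two spectral channels share a frame split at the
    horizontal midline (image-splitter geometry).
    """

    frames: np.ndarray
    channel_layout: str = "single"
    exposure_ms: float = 10.0
    pixel_size: float = 2.34  # µm/px
    frame_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError("frames must be a 3-D (t, row, col) array")
        if self.frames.size and self.frames.min() < 0:
            raise InputError("intensities must be nonnegative")
        if self.channel_layout not in ("single", "side-by-side"):
            raise InputError(f"unknown channel layout {self.channel_layout!r}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate

    def split_channels(self) -> tuple["ImageStack", "ImageStack"]:
        """Split a side-by-side dual-view frame into (left, right) stacks."""
        if self.channel_layout != "side-by-side":
            raise InputError("stack is not side-by-side dual channel")
        half = self.frames.shape[2] // 2
        mk = lambda fr: ImageStack(fr, "single", self.exposure_ms, self.pixel_size, self.frame_rate)
        return mk(self.frames[:, :, :half]), mk(self.frames[:, :, half : 2 * half])


@dataclass
class Ethogram:
    """Per-frame behavioral-state labels with aligned numeric channels."""

    time: np.ndarray
    state: np.ndarray  # categorical labels, one per frame
    velocity: np.ndarray | None = None  # µm/s
    pump_rate: np.ndarray | None = None  # Hz
    prey_signal: np.ndarray | None = None  # unitless

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.state = np.asarray(self.state, dtype=object)
        if len(self.state) != len(self.time):
            raise InputError("state and time lengths differ")
        for name in ("velocity", "pump_rate", "prey_signal"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.time):
                    raise InputError(f"{name} not aligned with time")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# pose tables (DeepLabCut three-header-row CSV dialect)
# ---------------------------------------------------------------------------

_COORD_COLS = ("x", "y", "likelihood")


def read_pose_table(
    path: str | Path, pixel_size: float = 1.0, frame_rate: float = 1.0, scorer: str | None = None
) -> PoseTrack:
    """Read a pose table in the scorer/bodyparts/coords CSV dialect.

    Missing coordinate cells become NaN with likelihood 0.  ``frame_rate``
    converts frame indices into seconds (the dialect itself carries no time
    column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a scorer/bodyparts/coords table ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected three header rows (scorer/bodyparts/coords)")
    parts: list[str] = []
    for _, part, _ in df.columns:
        if part not in parts:
            parts.append(part)
    for part in parts:
        coords = {c for _, p, c in df.columns if p == part}
        missing = set(_COORD_COLS) - coords
        if missing:
            raise FormatError(
                f"{path}: body part {part!r} lacks column(s) {sorted(missing)} in the coords header row"
            )
    n = len(df)
    x = np.full((n, len(parts)), np.nan)
    y = np.full((n, len(parts)), np.nan)
    lk = np.zeros((n, len(parts)))
    sc = df.columns[0][0]
    for j, part in enumerate(parts):
        x[:, j] = pd.to_numeric(df[(sc, part, "x")], errors="coerce")
        y[:, j] = pd.to_numeric(df[(sc, part, "y")], errors="coerce")
        lk[:, j] = pd.to_numeric(df[(sc, part, "likelihood")], errors="coerce").fillna(0.0)
    lk[~np.isfinite(x) | ~np.isfinite(y)] = 0.0
    frame_index = df.index.to_numpy(dtype=int)
    return PoseTrack(
        frame_index=frame_index,
        time=frame_index / float(frame_rate),
        parts=tuple(parts),
        x=x,
        y=y,
        likelihood=lk,
        pixel_size=pixel_size,
    )


def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "btk") -> Path:
    """Write ``track`` so that :func:`read_pose_table` round-trips it.

    NaN coordinates are serialized as empty cells and come back with
    likelihood 0 (the convention for missing detections).
    """
    path = Path(path)
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, c) for part in track.parts for c in _COORD_COLS],
        names=("scorer", "bodyparts", "coords"),
    )
    data = np.empty((len(track), 3 * track.n_parts))
    for j in range(track.n_parts):
        data[:, 3 * j] = track.x[:, j]
        data[:, 3 * j + 1] = track.y[:, j]
        data[:, 3 * j + 2] = track.likelihood[:, j]
    df = pd.DataFrame(data, index=pd.Index(track.frame_index, name=None), columns=cols)
    df.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# stage logs, ethograms, stacks, config
# ---------------------------------------------------------------------------

def read_stage_log(path: str | Path) -> StageLog:
    """Read a stage log CSV with columns time_s, x_mm, y_mm, moving."""
    df = pd.read_csv(path)
    required = {"time_s", "x_mm", "y_mm", "moving"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: stage log needs columns {sorted(required)}")
    return StageLog(df["time_s"], df["x_mm"], df["y_mm"], df["moving"].astype(bool))


def write_stage_log(log: StageLog, path: str | Path) -> Path:
    pd.DataFrame(
        {"time_s": log.time, "x_mm": log.stage_x, "y_mm": log.stage_y, "moving": log.moving_flag}
    ).to_csv(path, index=False)
    return Path(path)


def read_ethogram(path: str | Path) -> Ethogram:
    """Read an ethogram CSV with time_s, state and optional numeric channels."""
    df = pd.read_csv(path)
    if not {"time_s", "state"}.issubset(df.columns):
        raise FormatError(f"{path}: ethogram needs columns time_s, state")
    opt = {name: df[col] for name, col in
           (("velocity", "velocity_um_s"), ("pump_rate", "pump_rate_hz"), ("prey_signal", "prey_signal"))
           if col in df.columns}
    return Ethogram(df["time_s"], df["state"].to_numpy(dtype=object), **opt)


def write_ethogram(eth: Ethogram, path: str | Path) -> Path:
    cols = {"time_s": eth.time, "state": eth.state}
    if eth.velocity is not None:
        cols["velocity_um_s"] = eth.velocity
    if eth.pump_rate is not None:
        cols["pump_rate_hz"] = eth.pump_rate
    if eth.prey_signal is not None:
        cols["prey_signal"] = eth.prey_signal
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def read_stack(path: str | Path, **meta) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, **meta)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    tifffile.imwrite(path, stack.frames)
    return Path(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# camera frame -> laboratory frame
# ---------------------------------------------------------------------------

def merge_with_stage(
    track: PoseTrack,
    log: StageLog,
    fov_center_px: tuple[float, float],
    tolerance: float | None = None,
) -> PoseTrack:
    """Transform camera-pixel coordinates into laboratory mm coordinates.

    Each frame is paired with the nearest-in-time stage sample (within
    ``tolerance``, default half the frame period), and

        lab_x = stage_x + (x - fov_center_x) * pixel_size / 1000

    (and likewise for y).  Frames whose matched stage sample was moving are
    flagged in ``moving`` — downstream analyses may discard them, mirroring
    the tracker's policy of ignoring frames acquired during stage motion.
    """
    if len(track) == 0:
        raise InputError("empty pose track")
    if track.time[0] > log.time[-1] or track.time[-1] < log.time[0]:
        raise AlignmentError(
            f"pose track ({track.time[0]:.3f}-{track.time[-1]:.3f} s) and stage log "
            f"({log.time[0]:.3f}-{log.time[-1]:.3f} s) do not overlap in time"
        )
    if tolerance is None:
        dt = np.median(np.diff(track.time)) if len(track) > 1 else np.inf
        tolerance = dt / 2
    idx = np.searchsorted(log.time, track.time)
    idx = np.clip(idx, 1, len(log) - 1)
    left_closer = (track.time - log.time[idx - 1]) < (log.time[idx] - track.time)
    idx = np.where(left_closer, idx - 1, idx)
    gap = np.abs(log.time[idx] - track.time)
    if np.any(gap > tolerance + 1e-12):
        bad = int(np.argmax(gap))
        raise AlignmentError(
            f"frame {track.frame_index[bad]} at t={track.time[bad]:.3f} s has no stage sample "
            f"within {tolerance:.4f} s (nearest gap {gap[bad]:.4f} s)"
        )
    cx, cy = fov_center_px
    scale = track.pixel_size / 1000.0  # µm/px -> mm/px
    lab_x = log.stage_x[idx][:, None] + (track.x - cx) * scale
    lab_y = log.stage_y[idx][:, None] + (track.y - cy) * scale
    return replace(track, x=lab_x, y=lab_y, units="mm", moving=log.moving_flag[idx])
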