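"""Pose cleaning, body straightening, swing detection and trajectory metrics.

The locomotion pipeline for multi-legged walkers (developed for tardigrade
recordings, but agnostic to the species):

1. gate pose estimates by likelihood (< 0.7 by default) and fill gaps by
   linear interpolation in time;
2. build a body centerline per frame from the front point, the left/right
   midpoint of each leg pair, and the rear point, resampled to points
   equally spaced in arc length;
3. express each body part in straightened coordinates — the arc-length
   position of the nearest centerline point (anterior-posterior position)
   and the Euclidean distance to it (lateral distance D);
4. detect leg swings on the protraction-positive anterior-posterior series:
   a swing onset is the peak of the first derivative (maximum protraction
   speed) and its offset the following trough of the second derivative
   (maximum deceleration);
5. derive duty factors (stance duration / stride duration) and compare
   automatic with manual annotations (frame accuracy, precision,
   onset/offset deltas, Pearson r combined across animals by the Fisher-z
   transform, p-values combined by Fisher's method);
6. trajectory behaviors: speed from stage coordinates, sharp-angle
   reversals and intermediate-angle turns, and the odortaxis success rule
   (entered and remained within 5 mm of the target within 5 minutes).

Swing intervals use the half-open convention ``[onset, offset)`` in frames
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, stats

from .errors import DegenerateGeometryError, InputError, ParameterError
from .io_core import PoseTrack, StageLog
from .synthetic_data import Trajectory

__all__ = [
    "StraightenedPose",
    "SwingAnnotation",
    "AgreementReport",
    "preprocess_pose",
    "centerline_anchors",
    "build_centerline",
    "straighten",
    "straighten_track",
    "swing_series",
    "detect_swings",
    "NOISY_DETECTOR",
    "annotate_swings",
    "duty_factor",
    "intervals_to_frames",
    "compare_annotations",
    "fisher_z_mean",
    "fisher_combine_pvalues",
    "velocity_from_stage",
    "detect_reversals",
    "detect_turns",
    "odortaxis_success",
    "gait_diagram",
]


@dataclass
class StraightenedPose:
    """Body parts in body-centerline coordinates (µm).

    ``centerlines``: (n_frames, n_points, 2) equally spaced points;
    ``ap_position``: arc-length distance from the front anchor to the
    nearest centerline point, per part per frame; ``lateral``: Euclidean
    distance of the part to that point.
    """

    parts: tuple[str, ...]
    centerlines: np.ndarray
    ap_position: np.ndarray
    lateral: np.ndarray
    body_length: np.ndarray  # per frame, µm

    def part_ap(self, part: str) -> np.ndarray:
        return self.ap_position[:, self.parts.index(part)]


@dataclass
class SwingAnnotation:
    """Per-leg swing intervals ``[onset, offset)`` in frames."""

    intervals: dict[str, list[tuple[int, int]]]
    frame_rate: float
    n_frames: int

    def swing_frames(self, part: str) -> np.ndarray:
        return intervals_to_frames(self.intervals[part], self.n_frames)


@dataclass
class AgreementReport:
    """Automatic-vs-manual swing agreement for one animal."""

    accuracy: float
    precision: float
    onset_deltas: np.ndarray  # frames, auto − manual, matched events
    offset_deltas: np.ndarray
    r: float  # Pearson r on matched on/offset frame indices
    p: float
    n_matched: int


# ---------------------------------------------------------------------------
# cleaning and straightening
# ---------------------------------------------------------------------------

def preprocess_pose(
    track: PoseTrack, likelihood_threshold: float = 0.7
) -> tuple[PoseTrack, np.ndarray]:
    """Interpolate low-confidence detections and compute the center of mass.

    Positions whose likelihood falls below ``likelihood_threshold`` (or that
    are non-finite) are linearly interpolated in time per part, holding the
    edge values.  The center of mass is the per-frame mean of all parts.
    Returns ``(cleaned_track, com)`` with ``com`` of shape (n_frames, 2).
    """
    if len(track) < 2:
        raise InputError("need at least 2 frames")
    x = track.x.copy()
    y = track.y.copy()
    good = (track.likelihood >= likelihood_threshold) & np.isfinite(x) & np.isfinite(y)
    t = track.time
    for j, part in enumerate(track.parts):
        g = good[:, j]
        if not g.any():
            raise InputError(f"part {part!r} is below threshold for the entire track")
        if not g.all():
            x[:, j] = np.interp(t, t[g], x[g, j])
            y[:, j] = np.interp(t, t[g], y[g, j])
    from dataclasses import replace

    cleaned = replace(track, x=x, y=y)
    com = np.stack([x.mean(axis=1), y.mean(axis=1)], axis=1)
    return cleaned, com


def centerline_anchors(track: PoseTrack, frame: int) -> np.ndarray:
    """Anchor points for one frame: front, leg-pair midpoints, rear.

    Leg pairs are recognised by the ``leg{i}_left`` / ``leg{i}_right``
    naming convention and ordered anterior to posterior.
    """
    parts = track.parts
    if "front" not in parts or "rear" not in parts:
        raise InputError("track needs 'front' and 'rear' parts")
    pairs: dict[int, dict[str, int]] = {}
    for j, p in enumerate(parts):
        if p.startswith("leg") and "_" in p:
            num, side = p[3:].split("_", 1)
            pairs.setdefault(int(num), {})[side] = j
    if not pairs:
        raise InputError("no leg pairs found (expected parts named leg{i}_left/right)")
    pts = [np.array([track.x[frame, parts.index("front")], track.y[frame, parts.index("front")]])]
    for num in sorted(pairs):
        idx = list(pairs[num].values())
        pts.append(np.array([track.x[frame, idx].mean(), track.y[frame, idx].mean()]))
    pts.append(np.array([track.x[frame, parts.index("rear")], track.y[frame, parts.index("rear")]]))
    return np.vstack(pts)


def build_centerline(anchors: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Resample a polyline through the anchors to equally spaced points.

    Interpolates linearly along cumulative arc length and returns
    ``n_points`` points whose arc-length spacing is constant.
    """
    a = np.asarray(anchors, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or len(a) < 2:
        raise DegenerateGeometryError("need at least two 2-D anchor points")
    seg = np.linalg.norm(np.diff(a, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateGeometryError("anchors are coincident; centerline has zero length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    f = interpolate.interp1d(s, a, axis=0, kind="linear")
    return f(np.linspace(0.0, total, n_points))


def straighten(
    parts_xy: np.ndarray, centerline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Straightened coordinates of parts against one centerline.

    For each part the nearest point ``cl_p`` on the centerline is found
    (continuous projection onto the polyline, so ap does not quantize to
    the point spacing); ``ap_position`` is the arc length from the front
    (first centerline point) to ``cl_p`` and ``lateral`` the Euclidean
    distance to it.
    """
    cl = np.asarray(centerline, dtype=float)
    pts = np.atleast_2d(np.asarray(parts_xy, dtype=float))
    a = cl[:-1]  # segment starts
    d = np.diff(cl, axis=0)  # segment vectors
    seg_len = np.linalg.norm(d, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    # continuous projection of each part onto each polyline segment
    rel = pts[:, None, :] - a[None, :, :]
    denom = np.where(seg_len > 0, seg_len**2, 1.0)
    t = np.clip((rel * d[None]).sum(axis=2) / denom, 0.0, 1.0)
    foot = a[None] + t[:, :, None] * d[None]
    d2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    idx = np.arange(len(pts))
    ap = arc[nearest] + t[idx, nearest] * seg_len[nearest]
    lateral = np.sqrt(d2[idx, nearest])
    return ap, lateral


def straighten_track(track: PoseTrack, n_points: int = 100) -> StraightenedPose:
    """Straighten every frame of a (cleaned) pose track; output in µm."""
    scale = track.pixel_size if track.units == "px" else 1000.0
    n = len(track)
    n_parts = track.n_parts
    cls = np.empty((n, n_points, 2))
    ap = np.empty((n, n_parts))
    lat = np.empty((n, n_parts))
    length = np.empty(n)
    for i in range(n):
        anchors = centerline_anchors(track, i) * scale
        cl = build_centerline(anchors, n_points)
        cls[i] = cl
        pts = np.stack([track.x[i] * scale, track.y[i] * scale], axis=1)
        ap[i], lat[i] = straighten(pts, cl)
        length[i] = np.linalg.norm(np.diff(cl, axis=0), axis=1).sum()
    return StraightenedPose(track.parts, cls, ap, lat, length)


def swing_series(straightened: StraightenedPose, part: str) -> np.ndarray:
    """Protraction-positive anterior-posterior series for swing detection.

    ``ap_position`` measures distance from the head, so protraction (the
    swing) decreases it; the detector expects a series that rises during
    protraction, hence ``body_length − ap``.
    """
    return straightened.body_length - straightened.part_ap(part)


# ---------------------------------------------------------------------------
# swing detection and duty factor
# ---------------------------------------------------------------------------

#: Detector settings for pose-estimation-grade noise (documented preset):
#: heavier Gaussian-derivative smoothing and deepest-trough offset pairing.
NOISY_DETECTOR = {"smooth_sigma": 3.0, "prominence_k": 3.0, "pairing": "deepest"}


def detect_swings(
    ap: np.ndarray,
    frame_rate: float,
    smooth_window: int = 5,
    polyorder: int = 3,
    prominence_k: float = 2.0,
    smooth_sigma: float | None = None,
    pairing: str = "first",
) -> list[tuple[int, int]]:
    """Swing intervals of one leg from its protraction-positive ap series.

    Onsets are prominent maxima of the first derivative (protraction
    speed); each onset is paired with a subsequent trough of the second
    derivative (maximum deceleration, the last swing frame, so the stored
    half-open offset is ``trough + 1``).  Derivatives come from a
    Savitzky-Golay filter (``smooth_window``/``polyorder``; the default
    window 5 is near-exact on clean series) or, when ``smooth_sigma`` is
    given, from Gaussian-derivative filters — the robust choice for
    pose-estimation-grade noise (see :data:`NOISY_DETECTOR`).  Peak
    prominence adapts to the data as ``prominence_k × MAD`` of the
    respective derivative.  ``pairing`` selects the first subsequent
    trough (default) or the deepest trough before the next onset, which
    resists spurious shallow troughs in noisy series.  A new onset before
    an offset closes the previous swing; a trailing unpaired onset is
    dropped.  No swings is a valid (empty) result.
    """
    if pairing not in ("first", "deepest"):
        raise ParameterError("pairing must be 'first' or 'deepest'")
    y = np.asarray(ap, dtype=float)
    if len(y) < max(smooth_window, 5):
        return []
    if smooth_sigma is not None:
        from scipy.ndimage import gaussian_filter1d

        v = gaussian_filter1d(y, smooth_sigma, order=1)
        a = gaussian_filter1d(y, smooth_sigma, order=2)
    else:
        win = min(
            smooth_window if smooth_window % 2 else smooth_window + 1,
            len(y) - (1 - len(y) % 2),
        )
        if win > polyorder and win >= 5:
            v = signal.savgol_filter(y, win, polyorder, deriv=1)
            a = signal.savgol_filter(y, win, polyorder, deriv=2)
        else:
            v = np.gradient(y)
            a = np.gradient(v)

    def scale(z: np.ndarray) -> float:
        # robust spread with a dispersion floor: on clean gaits more than half
        # the derivative samples can be identical, collapsing the MAD to 0
        mad = 1.4826 * float(np.median(np.abs(z - np.median(z))))
        return max(mad, 0.2 * float(np.std(z)), 1e-12)

    onsets, _ = signal.find_peaks(v, prominence=prominence_k * scale(v))
    troughs, _ = signal.find_peaks(-a, prominence=prominence_k * scale(a))

    intervals: list[tuple[int, int]] = []
    for i, on in enumerate(onsets):
        nxt = onsets[i + 1] if i + 1 < len(onsets) else None
        after = troughs[troughs > on]
        if nxt is not None:
            after = after[after < nxt]
        if after.size:
            pick = after[np.argmin(a[after])] if pairing == "deepest" else after[0]
            off = int(pick) + 1  # trough is the last swing frame
        elif nxt is not None:
            off = int(nxt)  # next onset forces closure of this swing
        else:
            continue  # unpaired onset at track end
        if off > on:
            intervals.append((int(on), off))
    return intervals


def annotate_swings(
    straightened: StraightenedPose,
    legs: list[str],
    frame_rate: float,
    **detector_kw,
) -> SwingAnnotation:
    """Run swing detection on each leg's protraction series."""
    intervals = {
        leg: detect_swings(swing_series(straightened, leg), frame_rate, **detector_kw)
        for leg in legs
    }
    n_frames = straightened.ap_position.shape[0]
    return SwingAnnotation(intervals, frame_rate, n_frames)


def duty_factor(
    intervals: list[tuple[int, int]], n_frames: int | None = None
) -> float:
    """Mean duty factor over complete strides of one leg.

    A stride runs onset-to-onset; its stance duration is the stride minus
    the swing duration, so ``duty = 1 − swing/stride`` per stride.  Returns
    NaN when no complete stride exists.
    """
    if len(intervals) < 2:
        return float("nan")
    duties = []
    for (on0, off0), (on1, _) in zip(intervals[:-1], intervals[1:]):
        stride = on1 - on0
        swing = off0 - on0
        if stride > 0:
            duties.append(1.0 - swing / stride)
    return float(np.mean(duties)) if duties else float("nan")


def intervals_to_frames(intervals: list[tuple[int, int]], n_frames: int) -> np.ndarray:
    """Boolean per-frame swing labels under the ``[onset, offset)`` convention."""
    out = np.zeros(n_frames, dtype=bool)
    for on, off in intervals:
        out[max(on, 0) : min(off, n_frames)] = True
    return out


# ---------------------------------------------------------------------------
# annotation agreement
# ---------------------------------------------------------------------------

def _match_events(auto: np.ndarray, manual: np.ndarray, tolerance: int):
    """Greedy nearest matching of event frames within ±tolerance."""
    pairs = []
    used = np.zeros(len(auto), dtype=bool)
    for m in manual:
        if len(auto) == 0:
            break
        d = np.abs(auto - m).astype(float)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            used[j] = True
            pairs.append((int(auto[j]), int(m)))
    return pairs


def compare_annotations(
    auto: list[tuple[int, int]],
    manual: list[tuple[int, int]],
    n_frames: int,
    tolerance: int = 5,
) -> AgreementReport:
    """Agreement between automatic and manual swing annotations (one animal).

    Frame accuracy is the fraction of frames with matching swing/stance
    labels; precision is TP/(TP+FP) on swing frames.  Events (onsets and
    offsets) are matched to the nearest counterpart within ``±tolerance``
    frames; the report carries the matched deltas (auto − manual) and the
    Pearson r between matched auto and manual frame indices, onsets and
    offsets pooled.
    """
    fa = intervals_to_frames(auto, n_frames)
    fm = intervals_to_frames(manual, n_frames)
    accuracy = float((fa == fm).mean())
    tp = int((fa & fm).sum())
    fp = int((fa & ~fm).sum())
    precision = tp / (tp + fp) if (tp + fp) else float("nan")

    on_pairs = _match_events(np.array([i[0] for i in auto]), np.array([i[0] for i in manual]), tolerance)
    off_pairs = _match_events(np.array([i[1] for i in auto]), np.array([i[1] for i in manual]), tolerance)
    onset_deltas = np.array([a - m for a, m in on_pairs])
    offset_deltas = np.array([a - m for a, m in off_pairs])

    all_auto = np.array([a for a, _ in on_pairs] + [a for a, _ in off_pairs], dtype=float)
    all_manual = np.array([m for _, m in on_pairs] + [m for _, m in off_pairs], dtype=float)
    if len(all_auto) >= 2 and all_auto.std() > 0 and all_manual.std() > 0:
        r, p = stats.pearsonr(all_auto, all_manual)
        # upper-tailed: the hypothesis of interest is positive correlation
        p = p / 2.0 if r > 0 else 1.0 - p / 2.0
    else:
        r, p = float("nan"), float("nan")
    return AgreementReport(
        accuracy=accuracy,
        precision=precision,
        onset_deltas=onset_deltas,
        offset_deltas=offset_deltas,
        r=float(r),
        p=float(p),
        n_matched=len(all_auto),
    )


def fisher_z_mean(rs) -> float:
    """Average correlation coefficients through the Fisher-z transform."""
    rs = np.asarray(rs, dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15)))))


def fisher_combine_pvalues(ps) -> tuple[float, int, float]:
    """Fisher's method: ``χ² = −2 Σ ln p`` with 2k degrees of freedom."""
    ps = np.asarray(ps, dtype=float)
    ps = ps[np.isfinite(ps)]
    if ps.size == 0:
        return float("nan"), 0, float("nan")
    chi2 = float(-2.0 * np.sum(np.log(np.clip(ps, 1e-300, 1.0))))
    df = 2 * len(ps)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# trajectory behaviors
# ---------------------------------------------------------------------------

def velocity_from_stage(
    time: np.ndarray | StageLog,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    smooth_window: int = 1,
) -> np.ndarray:
    """Central-difference speed from stage (or lab-frame) coordinates, µm/s.

    Accepts a :class:`StageLog` or explicit time/x/y arrays in s and mm.
    ``smooth_window > 1`` applies a moving average to the speed.
    """
    if isinstance(time, StageLog):
        log = time
        t, xx, yy = log.time, log.stage_x, log.stage_y
    else:
        t, xx, yy = (np.asarray(a, dtype=float) for a in (time, x, y))
    if len(t) < 2:
        raise InputError("need at least 2 samples")
    vx = np.gradient(xx, t)
    vy = np.gradient(yy, t)
    speed = np.hypot(vx, vy) * 1000.0  # mm/s -> µm/s
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def _window_headings(traj: Trajectory, window: float):
    """Mean displacement direction before and after each sample."""
    t, x, y = traj.time, traj.x, traj.y
    n = len(t)
    pre = np.full((n, 2), np.nan)
    post = np.full((n, 2), np.nan)
    for i in range(n):
        j0 = np.searchsorted(t, t[i] - window)
        j1 = np.searchsorted(t, t[i] + window, side="right") - 1
        if j0 < i:
            pre[i] = (x[i] - x[j0], y[i] - y[j0])
        if j1 > i:
            post[i] = (x[j1] - x[i], y[j1] - y[i])
    return pre, post


def _turn_angles(traj: Trajectory, window: float, min_step: float):
    pre, post = _window_headings(traj, window)
    dot = (pre * post).sum(axis=1)
    cross = pre[:, 0] * post[:, 1] - pre[:, 1] * post[:, 0]
    norm = np.linalg.norm(pre, axis=1) * np.linalg.norm(post, axis=1)
    valid = np.isfinite(norm) & (np.linalg.norm(pre, axis=1) > min_step) & (
        np.linalg.norm(post, axis=1) > min_step
    )
    angle = np.full(len(traj), np.nan)
    angle[valid] = np.degrees(np.arctan2(cross[valid], dot[valid]))
    return angle  # signed, (-180, 180]


def _merge_events(mask: np.ndarray, time: np.ndarray) -> list[tuple[float, float]]:
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            out.append((float(time[start]), float(time[prev])))
            start = i
        prev = i
    out.append((float(time[start]), float(time[prev])))
    return out


def detect_reversals(
    traj: Trajectory,
    angle_threshold: float = 150.0,
    window: float = 1.0,
    min_step: float = 1e-6,
) -> list[tuple[float, float]]:
    """Reversal intervals: heading change within ``window`` s > threshold.

    The heading before and after each sample is the net displacement over
    ``window`` seconds; samples where the unsigned angle between the two
    exceeds ``angle_threshold`` degrees (default 150°, a near-complete
    direction flip) are merged into intervals.
    """
    angle = _turn_angles(traj, window, min_step)
    mask = np.abs(angle) > angle_threshold
    mask &= np.isfinite(angle)
    return _merge_events(mask, traj.time)


def detect_turns(
    traj: Trajectory,
    angle_band: tuple[float, float] = (60.0, 150.0),
    window: float = 1.0,
    min_step: float = 1e-6,
) -> list[tuple[float, float, float]]:
    """Turn events: heading change in the intermediate angle band.

    Sudden directional changes whose unsigned angle lies in ``angle_band``
    (default 60°-150°; sharper changes are reversals).  Returns
    ``(t_start, t_end, signed_angle)`` per event, the signed angle taken at
    the event's largest deflection (positive = counter-clockwise).  Band
    crossings produced by a heading window straddling a reversal are not
    turns: events within ``window`` seconds of a reversal-grade sample are
    suppressed.
    """
    angle = _turn_angles(traj, window, min_step)
    mask = np.isfinite(angle) & (np.abs(angle) >= angle_band[0]) & (np.abs(angle) < angle_band[1])
    reversal_times = traj.time[np.isfinite(angle) & (np.abs(angle) >= angle_band[1])]
    events = []
    for t0, t1 in _merge_events(mask, traj.time):
        if reversal_times.size and np.min(
            np.minimum(np.abs(reversal_times - t0), np.abs(reversal_times - t1))
        ) <= window:
            continue
        sel = (traj.time >= t0) & (traj.time <= t1)
        seg = angle[sel]
        events.append((t0, t1, float(seg[np.argmax(np.abs(seg))])))
    return events


def odortaxis_success(
    traj: Trajectory,
    target_xy: tuple[float, float],
    radius: float = 5.0,
    horizon: float = 300.0,
) -> bool:
    """Whether the animal entered and remained within the target radius.

    True iff, restricted to the first ``horizon`` seconds, there exists an
    entry time after which the distance to ``target_xy`` stays ≤ ``radius``
    through the end of the (clipped) recording.
    """
    sel = traj.time - traj.time[0] <= horizon
    d = np.hypot(traj.x[sel] - target_xy[0], traj.y[sel] - target_xy[1])
    return bool(d.size and d[-1] <= radius)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def gait_diagram(annotation: SwingAnnotation, legs: list[str] | None = None, ax=None):
    """Hildebrand-style gait diagram: stance as filled bars per leg."""
    import matplotlib.pyplot as plt

    legs = legs or list(annotation.intervals)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(legs) + 1))
    dt = 1.0 / annotation.frame_rate
    for row, leg in enumerate(legs):
        stance = ~annotation.swing_frames(leg)
        for t0, t1 in _merge_events(stance, np.arange(annotation.n_frames) * dt):
            ax.fill_between([t0, t1 + dt], row + 0.1, row + 0.9, color="k")
    ax.set_yticks(np.arange(len(legs)) + 0.5, legs)
    ax.set_xlabel("time (s)")
    ax.set_ylim(0, len(legs))
    return ax
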