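"""Prey-contact quantification at the predator's mouth.

The prey (GFP-labeled) becomes visible in the green channel when it enters
the region in front of the predator's mouth opening.  The per-frame prey
signal is a contrast statistic over a 34 µm circular mask centered on the
anterior end of the predator's centerline:

    preysignal = (GFP_p95 − GFP_p5) / GFP_p5

(percentiles with the linear-interpolation convention).  For bite-aligned
analysis each track is normalized to its own baseline, the mean prey signal
between 15 and 5 s before bite onset:

    preysignal(%) = 100 · (preysignal − baseline) / baseline

Tracks whose modal behavioral state before bite onset is already biting or
feeding are excluded (the contact had begun before the alignment point),
and the rise is tested with an upper-tailed paired t-test comparing the
−15..−5 s and 0..15 s windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError, ParameterError
from .io_core import Ethogram, ImageStack

__all__ = [
    "PreyTrace",
    "mouth_mask",
    "prey_signal",
    "prey_signal_trace",
    "normalize_to_baseline",
    "align_at_bite_onset",
    "bite_rise_test",
]

BITING_STATES = ("predatory_biting", "biting")
FEEDING_STATES = ("predatory_feeding", "feeding")


@dataclass
class PreyTrace:
    """Per-frame prey signal for one predator track."""

    time: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None  # percent
    bite_onset: float | None = None  # s
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.time):
            raise InputError("raw and time lengths differ")

    def __len__(self) -> int:
        return len(self.time)


def mouth_mask(
    centerline: np.ndarray,
    frame_shape: tuple[int, int],
    pixel_size: float,
    diameter_um: float = 34.0,
) -> np.ndarray:
    """Circular mask at the anterior end of the predator's centerline.

    ``centerline`` is ordered anterior-first, in (row, col) pixels.  The
    mask has the stated physical diameter (34 µm by default, the width of
    the mouth region); a zero diameter degenerates to the single nearest
    pixel.  A mask clipped by the frame edge triggers a warning; an
    anterior point outside the frame is an error.
    """
    cl = np.asarray(centerline, dtype=float)
    if cl.ndim != 2 or cl.shape[1] != 2:
        raise InputError("centerline must be an (n, 2) array of (row, col) points")
    if diameter_um < 0:
        raise ParameterError("diameter must be nonnegative")
    h, w = frame_shape
    r0, c0 = cl[0]
    if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
        raise InputError(f"anterior centerline point ({r0:.1f}, {c0:.1f}) lies outside the frame")
    radius_px = (diameter_um / 2.0) / pixel_size
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    if radius_px == 0:
        mask = np.zeros(frame_shape, dtype=bool)
        mask[int(round(r0)), int(round(c0))] = True
        return mask
    mask = d2 <= radius_px**2
    if r0 - radius_px < 0 or r0 + radius_px > h - 1 or c0 - radius_px < 0 or c0 + radius_px > w - 1:
        warnings.warn("mouth mask clipped by the frame edge", stacklevel=2)
    return mask


def prey_signal(gfp_frame: np.ndarray, mask: np.ndarray) -> float:
    """Percentile-contrast prey signal over masked pixels.

    ``(p95 − p5) / p5`` with linear-interpolation percentiles; a 5th
    percentile ≤ 0 makes the statistic undefined and raises
    :class:`InputError` (callers flag and drop such frames).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty mask")
    vals = np.asarray(gfp_frame, dtype=float)[mask]
    p5, p95 = np.percentile(vals, [5, 95])
    if p5 <= 0:
        raise InputError("5th percentile is nonpositive; prey signal undefined")
    return float((p95 - p5) / p5)


def prey_signal_trace(stack: ImageStack, mask: np.ndarray) -> PreyTrace:
    """Per-frame prey signal over a fixed mask; undefined frames become NaN."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty mask")
    vals = stack.frames[:, mask]  # (t, n_mask)
    p5 = np.percentile(vals, 5, axis=1)
    p95 = np.percentile(vals, 95, axis=1)
    raw = np.where(p5 > 0, (p95 - p5) / np.where(p5 > 0, p5, 1.0), np.nan)
    return PreyTrace(time=stack.time, raw=raw)


def normalize_to_baseline(
    trace: PreyTrace,
    bite_onset: float,
    baseline_window: tuple[float, float] = (-15.0, -5.0),
) -> PreyTrace:
    """Normalize a prey trace to its pre-bite baseline, in percent.

    The baseline is the mean raw signal over ``baseline_window`` seconds
    relative to ``bite_onset``.  An unavailable window or nonpositive
    baseline marks the trace excluded (with a reason) instead of raising.
    """
    t0 = bite_onset + baseline_window[0]
    t1 = bite_onset + baseline_window[1]
    trace.bite_onset = bite_onset
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        trace.excluded = True
        trace.exclusion_reason = (
            f"baseline window [{t0:.1f}, {t1:.1f}] s outside recording "
            f"[{trace.time[0]:.1f}, {trace.time[-1]:.1f}] s"
        )
        return trace
    sel = (trace.time >= t0) & (trace.time < t1) & np.isfinite(trace.raw)
    if not sel.any():
        trace.excluded = True
        trace.exclusion_reason = "no defined prey-signal frames in baseline window"
        return trace
    baseline = float(trace.raw[sel].mean())
    if baseline <= 0:
        trace.excluded = True
        trace.exclusion_reason = f"nonpositive baseline ({baseline:.3g})"
        return trace
    trace.normalized = 100.0 * (trace.raw - baseline) / baseline
    return trace


def _first_onset(eth: Ethogram) -> int | None:
    is_bite = np.isin(eth.state, BITING_STATES)
    idx = np.flatnonzero(is_bite)
    return int(idx[0]) if idx.size else None


def align_at_bite_onset(
    tracks: list[tuple[Ethogram, PreyTrace]],
    baseline_window: tuple[float, float] = (-15.0, -5.0),
) -> tuple[list[PreyTrace], dict]:
    """Align tracks at the first biting onset and apply the exclusion rule.

    For each (ethogram, prey-trace) pair, t = 0 is placed at the track's
    first biting frame; the prey trace is baseline-normalized there.
    Excluded from the aligned set: tracks without a biting state, tracks
    whose modal pre-onset behavioral state is biting or feeding (contact
    preceded the alignment point), and tracks whose baseline is
    unavailable.  Returns the aligned traces (time rebased so onset = 0)
    plus an exclusion report; an empty result is a valid outcome.
    """
    aligned: list[PreyTrace] = []
    report: dict[str, list] = {"excluded": [], "n_input": len(tracks)}
    for i, (eth, trace) in enumerate(tracks):
        onset_idx = _first_onset(eth)
        if onset_idx is None:
            report["excluded"].append((i, "no biting state in track"))
            continue
        onset_t = float(eth.time[onset_idx])
        pre_states = eth.state[:onset_idx]
        if len(pre_states):
            labels, counts = np.unique(pre_states.astype(str), return_counts=True)
            mode = labels[np.argmax(counts)]
            if mode in BITING_STATES + FEEDING_STATES:
                report["excluded"].append((i, f"pre-onset modal state is {mode!r}"))
                continue
        trace = normalize_to_baseline(trace, onset_t, baseline_window)
        if trace.excluded:
            report["excluded"].append((i, trace.exclusion_reason))
            continue
        trace.time = trace.time - onset_t
        trace.bite_onset = 0.0
        aligned.append(trace)
    report["n_aligned"] = len(aligned)
    return aligned, report


def bite_rise_test(
    aligned: list[PreyTrace],
    pre_window: tuple[float, float] = (-15.0, -5.0),
    post_window: tuple[float, float] = (0.0, 15.0),
):
    """Upper-tailed paired t-test for the prey-signal rise at bite onset.

    Per-track means of the normalized signal over the pre (−15..−5 s) and
    post (0..15 s) windows; undefined frames are dropped from the window
    means.  Returns ``(t, p, pre_means, post_means)``.
    """
    pre_means, post_means = [], []
    for trace in aligned:
        if trace.normalized is None:
            raise InputError("trace is not baseline-normalized")
        y = trace.normalized
        pre_sel = (trace.time >= pre_window[0]) & (trace.time < pre_window[1]) & np.isfinite(y)
        post_sel = (trace.time >= post_window[0]) & (trace.time < post_window[1]) & np.isfinite(y)
        if not (pre_sel.any() and post_sel.any()):
            continue
        pre_means.append(y[pre_sel].mean())
        post_means.append(y[post_sel].mean())
    if len(pre_means) < 2:
        raise InputError("need at least 2 tracks with both windows present")
    pre_arr, post_arr = np.asarray(pre_means), np.asarray(post_means)
    diff = post_arr - pre_arr
    if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
        warnings.warn("zero-variance, zero-mean differences; returning t=0, p=1", stacklevel=2)
        return 0.0, 1.0, pre_arr, post_arr
    res = stats.ttest_rel(post_arr, pre_arr, alternative="greater")
    return float(res.statistic), float(res.pvalue), pre_arr, post_arr
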