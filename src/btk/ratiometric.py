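"""Ratiometric calcium-signal extraction and stimulus statistics.

Pipeline: percentile background subtraction → Gaussian-blur + Otsu neuron
segmentation → per-frame mean traces for the signal (GCaMP) and reference
(mKate2/mCherry) channels → channel ratio and ΔR/R0:

    R = (F_sig / (F̄_sig + 1)) / (F_ref / (F̄_ref + 1)),   ΔR/R0 = (R - R̄)/R̄

The "+1" pedestal in the denominators is the literal published form and is
the default; ``pedestal="off"`` gives the conventional F/F̄ ratio, in which
any per-frame artifact multiplying both channels cancels exactly.

Also here: the kymograph motion correction used for crawling muscle
activity (per-location least-squares regression of the green on the red
channel), stimulus-aligned paired statistics, the reversal split and mixed
linear model for touch responses, pump-event detection for pharyngeal
recordings, and photobleaching summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .errors import InputError, ModelError, ParameterError, SegmentationError
from .io_core import ImageStack

__all__ = [
    "DualChannelTrace",
    "Kymograph",
    "StimulusProtocol",
    "subtract_background",
    "segment_neuron",
    "extract_traces",
    "ratiometric_signal",
    "motion_correct_kymograph",
    "align_and_test",
    "split_by_reversal",
    "mixed_effect_test",
    "detect_pump_events",
    "bleaching_summary",
]


@dataclass
class DualChannelTrace:
    """Paired signal/reference fluorescence time series."""

    time: np.ndarray
    F_sig: np.ndarray
    F_ref: np.ndarray
    R: np.ndarray | None = None
    dRR0: np.ndarray | None = None
    F_sig_mean: float | None = None
    F_ref_mean: float | None = None
    R_mean: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F_sig = np.asarray(self.F_sig, dtype=float)
        self.F_ref = np.asarray(self.F_ref, dtype=float)
        if not len(self.time) == len(self.F_sig) == len(self.F_ref):
            raise InputError("trace arrays must have equal length")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Kymograph:
    """Location x time intensity matrices for the green and red channels."""

    G: np.ndarray
    R: np.ndarray
    alpha: np.ndarray | None = None
    F_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.G.shape != self.R.shape:
            raise InputError("G and R must have the same (location, time) shape")


@dataclass
class StimulusProtocol:
    """Stimulus onsets and the windows used for paired statistics.

    Windows are (start, stop) in seconds relative to each onset; defaults
    are the prestimulus interval −10..0 s and the stimulus interval 0..1 s.
    """

    onsets: np.ndarray
    stimulus_duration: float = 1.0
    pre_window: tuple[float, float] = (-10.0, 0.0)
    response_window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        for w in (self.pre_window, self.response_window):
            if not (np.isfinite(w[0]) and np.isfinite(w[1]) and w[0] < w[1]):
                raise ParameterError("windows must be finite, increasing intervals")
        if self.pre_window[1] > self.response_window[0]:
            raise ParameterError("pre and response windows must not overlap")


# ---------------------------------------------------------------------------
# image operations
# ---------------------------------------------------------------------------

def subtract_background(stack: ImageStack, sample_stride: int = 100) -> ImageStack:
    """Subtract the pooled 50th-percentile background.

    The background is the median pixel intensity pooled over every
    ``sample_stride``-th frame (frame 0 alone if the stride exceeds the
    stack length); the result is clipped at zero.
    """
    if len(stack) == 0:
        raise InputError("empty stack")
    sample = stack.frames[::sample_stride]
    background = float(np.percentile(sample, 50))
    frames = np.clip(stack.frames.astype(float) - background, 0.0, None)
    return replace(stack, frames=frames)


def segment_neuron(frame: np.ndarray, blur_sd: float = 0.3) -> np.ndarray:
    """Segment the neuron in a background-subtracted frame.

    Gaussian blur (``blur_sd`` px), Otsu threshold, keep the largest
    connected component.  Raises :class:`SegmentationError` on blank frames.
    """
    frame = np.asarray(frame, dtype=float)
    blurred = gaussian(frame, sigma=blur_sd, preserve_range=True)
    if blurred.max() <= blurred.min():
        raise SegmentationError("frame is constant; nothing to segment")
    thr = threshold_otsu(blurred)
    above = blurred > thr
    if not above.any():
        raise SegmentationError("no pixel above the Otsu threshold")
    lab = label(above)
    props = regionprops(lab)
    biggest = max(props, key=lambda p: p.area)
    return lab == biggest.label


def extract_traces(
    stack_pair: tuple[ImageStack, ImageStack],
    masks: np.ndarray | list[np.ndarray],
) -> DualChannelTrace:
    """Mean within-mask intensity per channel per frame.

    ``masks`` is a single boolean mask applied to every frame or one mask
    per frame.  An empty per-frame mask yields NaN for that frame.
    """
    sig, ref = stack_pair
    if sig.frames.shape != ref.frames.shape:
        raise InputError("signal and reference stacks must share shape")
    n = len(sig)
    masks_arr = np.asarray(masks, dtype=bool)
    if masks_arr.ndim == 2:
        if masks_arr.shape != sig.frames.shape[1:]:
            raise InputError("mask shape does not match the frame shape")
        masks_arr = np.broadcast_to(masks_arr, sig.frames.shape)
    elif masks_arr.shape != sig.frames.shape:
        raise InputError("mask shape does not match the stack")
    f_sig = np.full(n, np.nan)
    f_ref = np.full(n, np.nan)
    for i in range(n):
        m = masks_arr[i]
        if m.any():
            f_sig[i] = sig.frames[i][m].mean()
            f_ref[i] = ref.frames[i][m].mean()
    return DualChannelTrace(time=sig.time, F_sig=f_sig, F_ref=f_ref)


# ---------------------------------------------------------------------------
# ratio and ΔR/R0
# ---------------------------------------------------------------------------

def ratiometric_signal(
    trace: DualChannelTrace,
    pedestal: str = "on",
    mean_window: tuple[float, float] | None = None,
) -> DualChannelTrace:
    """Compute R and ΔR/R0 from a dual-channel trace.

    With ``pedestal="on"`` (default) the published form is used:
    ``R = (F_sig/(F̄_sig+1)) / (F_ref/(F̄_ref+1))``; with ``pedestal="off"``
    the conventional ``(F_sig/F̄_sig) / (F_ref/F̄_ref)``.  Means F̄ and R̄
    are taken over ``mean_window`` (seconds; default the whole trace).
    """
    if pedestal not in ("on", "off"):
        raise ParameterError("pedestal must be 'on' or 'off'")
    if mean_window is None:
        sel = np.isfinite(trace.F_sig) & np.isfinite(trace.F_ref)
    else:
        sel = (
            (trace.time >= mean_window[0])
            & (trace.time < mean_window[1])
            & np.isfinite(trace.F_sig)
            & np.isfinite(trace.F_ref)
        )
    if not sel.any():
        raise InputError("no finite samples in the mean window")
    f_sig_mean = float(trace.F_sig[sel].mean())
    f_ref_mean = float(trace.F_ref[sel].mean())
    ped = 1.0 if pedestal == "on" else 0.0
    denom = trace.F_ref / (f_ref_mean + ped)
    bad = np.flatnonzero(np.isfinite(denom) & (denom == 0.0))
    if bad.size:
        raise InputError(f"zero reference denominator at frames {bad.tolist()[:10]}")
    r = (trace.F_sig / (f_sig_mean + ped)) / denom
    r_mean = float(r[sel].mean())
    drr0 = (r - r_mean) / r_mean
    return replace(
        trace, R=r, dRR0=drr0, F_sig_mean=f_sig_mean, F_ref_mean=f_ref_mean, R_mean=r_mean
    )


def motion_correct_kymograph(kymo: Kymograph) -> Kymograph:
    """Regress out shared motion from a kymograph, location by location.

    For each anterior-posterior location L, α(L) minimizes
    Σ_t (G(t) − α R(t))² — closed form α = Σ G·R / Σ R² — and the corrected
    signal is F_corr = (G − αR) − ⟨G − αR⟩ with ⟨·⟩ the time mean.
    """
    rr = np.einsum("lt,lt->l", kymo.R, kymo.R)
    dead = np.flatnonzero(rr == 0.0)
    if dead.size:
        raise InputError(f"reference channel identically zero at location(s) {dead.tolist()}")
    alpha = np.einsum("lt,lt->l", kymo.G, kymo.R) / rr
    resid = kymo.G - alpha[:, None] * kymo.R
    f_corr = resid - resid.mean(axis=1, keepdims=True)
    return replace(kymo, alpha=alpha, F_corr=f_corr)


# ---------------------------------------------------------------------------
# stimulus-aligned statistics
# ---------------------------------------------------------------------------

def _paired_t(pre: np.ndarray, post: np.ndarray, alternative: str = "two-sided"):
    """Paired t-test with the zero-variance convention p = 1."""
    diff = post - pre
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        warnings.warn("zero-variance paired differences; returning t=0, p=1", stacklevel=3)
        return 0.0, 1.0
    res = stats.ttest_rel(post, pre, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def align_and_test(
    traces: list[DualChannelTrace] | list[np.ndarray],
    protocol: StimulusProtocol,
    time: np.ndarray | None = None,
):
    """Align ΔR/R0 traces at stimulus onsets and run the paired test.

    ``traces`` are repeats — DualChannelTrace objects with ``dRR0`` set, or
    raw arrays with a shared ``time`` vector.  Every (trace, onset) pair is
    one repeat; repeats whose pre or response window falls outside the trace
    are excluded with a warning.  Returns ``(aligned, pre_means,
    response_means, t, p)`` where ``aligned`` is a dict with the aligned
    time base and matrix.
    """
    series: list[tuple[np.ndarray, np.ndarray]] = []
    for tr in traces:
        if isinstance(tr, DualChannelTrace):
            if tr.dRR0 is None:
                raise InputError("trace lacks dRR0; run ratiometric_signal first")
            series.append((tr.time, tr.dRR0))
        else:
            if time is None:
                raise InputError("raw arrays need an explicit time vector")
            series.append((np.asarray(time, dtype=float), np.asarray(tr, dtype=float)))

    lo = min(protocol.pre_window[0], protocol.response_window[0])
    hi = max(protocol.pre_window[1], protocol.response_window[1])
    pre_means, resp_means, snippets = [], [], []
    dt = np.median(np.diff(series[0][0]))
    rel = np.arange(lo, hi, dt)
    n_excluded = 0
    for t_vec, y in series:
        for onset in protocol.onsets:
            t0, t1 = onset + lo, onset + hi
            if t0 < t_vec[0] - dt / 2 or t1 > t_vec[-1] + dt / 2:
                n_excluded += 1
                continue
            pre_sel = (t_vec >= onset + protocol.pre_window[0]) & (t_vec < onset + protocol.pre_window[1])
            resp_sel = (t_vec >= onset + protocol.response_window[0]) & (
                t_vec < onset + protocol.response_window[1]
            )
            if not (pre_sel.any() and resp_sel.any()):
                n_excluded += 1
                continue
            pre_means.append(np.nanmean(y[pre_sel]))
            resp_means.append(np.nanmean(y[resp_sel]))
            snippets.append(np.interp(rel + onset, t_vec, y))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} repeat(s) with windows outside the trace", stacklevel=2)
    if len(pre_means) < 2:
        raise InputError("need at least 2 usable repeats")
    pre_arr, resp_arr = np.asarray(pre_means), np.asarray(resp_means)
    t_stat, p = _paired_t(pre_arr, resp_arr, "two-sided")
    aligned = {"time": rel, "matrix": np.vstack(snippets)}
    return aligned, pre_arr, resp_arr, t_stat, p


def split_by_reversal(
    repeat_onsets: np.ndarray,
    reversal_intervals: list[tuple[float, float]],
    window: float = 2.0,
):
    """Partition stimulus repeats by reversal occurrence near onset.

    A repeat belongs to the reversal group when any reversal interval
    intersects ``[onset, onset + window]`` (a reversal within ``window``
    seconds of stimulus onset).  Returns ``(reversal_idx, forward_idx)``.
    """
    onsets = np.atleast_1d(np.asarray(repeat_onsets, dtype=float))
    rev, fwd = [], []
    for i, onset in enumerate(onsets):
        hit = any(t0 <= onset + window and t1 >= onset for t0, t1 in reversal_intervals)
        (rev if hit else fwd).append(i)
    return np.array(rev, dtype=int), np.array(fwd, dtype=int)


def mixed_effect_test(
    post_stim_means: np.ndarray,
    reversal_flag: np.ndarray,
    animal_id: np.ndarray,
):
    """Random-intercept linear mixed model of post-stimulus activity.

    Fixed effect: the reversal flag (categorical); random intercept per
    animal.  Returns ``(coefficient, z, p)`` for the reversal effect, with
    a Wald z-test on the fixed-effect coefficient.
    """
    import statsmodels.api as sm

    y = np.asarray(post_stim_means, dtype=float)
    flag = np.asarray(reversal_flag).astype(int)
    groups = np.asarray(animal_id)
    if len(np.unique(groups)) < 2:
        raise ModelError("need at least two animals for a random-intercept model")
    if len(np.unique(flag)) < 2:
        raise ModelError("both reversal-flag levels must be present")
    exog = sm.add_constant(flag.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        fit = model.fit(reml=True)
    coef = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return coef, z, p


# ---------------------------------------------------------------------------
# pump events and photobleaching
# ---------------------------------------------------------------------------

def detect_pump_events(
    trace: np.ndarray,
    frame_rate: float,
    min_prominence: float,
    min_separation: float = 0.1,
):
    """Detect pharyngeal-pump peaks and the pumping rate.

    Local maxima with at least ``min_prominence`` prominence and
    ``min_separation`` seconds between events (the larger of two close
    peaks wins).  Returns ``(event_times, rate_hz)`` with
    ``rate = n_events / duration``.
    """
    y = np.asarray(trace, dtype=float)
    if len(y) < 3:
        return np.array([]), 0.0
    distance = max(int(round(min_separation * frame_rate)), 1)
    peaks, _ = signal.find_peaks(y, prominence=min_prominence, distance=distance)
    duration = len(y) / frame_rate
    return peaks / frame_rate, len(peaks) / duration


def bleaching_summary(
    mean_intensity: np.ndarray,
    time: np.ndarray | None = None,
    edge_fraction: float = 0.05,
):
    """Fractional intensity loss and fitted exponential time constant.

    ``reduction = 1 − mean(last 5%) / mean(first 5%)`` and τ from a
    least-squares fit of ``A·exp(−t/τ)``.  A non-decaying trace reports
    ``tau = inf``.  Returns ``(reduction, tau)``.
    """
    y = np.asarray(mean_intensity, dtype=float)
    if len(y) < 2:
        raise InputError("trace must have at least 2 samples")
    t = np.arange(len(y), dtype=float) if time is None else np.asarray(time, dtype=float)
    k = max(int(round(edge_fraction * len(y))), 1)
    first, last = y[:k].mean(), y[-k:].mean()
    if first <= 0:
        raise InputError("nonpositive initial mean intensity")
    reduction = 1.0 - last / first

    if reduction <= 1e-12:
        return float(reduction), float("inf")
    # log-linear initialisation, then nonlinear refinement
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) * 10.0
    from scipy.optimize import curve_fit

    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            y,
            p0=(float(np.exp(intercept)), float(tau0)),
            maxfev=10000,
        )
        tau = float(popt[1])
    except RuntimeError:
        tau = float(tau0)
    return float(reduction), tau
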