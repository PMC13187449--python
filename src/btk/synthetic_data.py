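"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is a pure function of its seed and emits the ground truth
alongside the dataset, so detection, ratiometric extraction, prey-contact
quantification and the tracking simulator can all be validated without any
external recordings.

Scientific content emulated:

* ``generate_gait_pose`` — multi-legged walking (default: eight legs in four
  pairs, a posterior-to-anterior stance wave with left/right antiphase, the
  tetrapod-like coordination of tardigrades) as a pose-estimation table with
  confidence dropouts and localization noise.
* ``generate_dual_channel_stack`` — a dual-color recording of a moving
  fluorescent emitter (GCaMP-like signal channel plus mKate2/mCherry-like
  reference) sharing multiplicative motion/focus artifacts, with green-only
  calcium transients, photobleaching, and Poisson + Gaussian noise.
* ``generate_predation_scene`` — a predator centerline with a bite-state
  ethogram and a green prey-fluorescence field that lights up inside the
  mouth region only during contact.
* ``generate_trajectory`` — correlated-random-walk animal paths feeding the
  closed-loop tracking simulator.
* ``odor_field`` — a 2-D instantaneous point-source diffusion kernel for
  odortaxis scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError
from .io_core import Ethogram, ImageStack, PoseTrack

__all__ = [
    "GaitParams",
    "SceneParams",
    "PredationParams",
    "GroundTruth",
    "Trajectory",
    "generate_gait_pose",
    "generate_dual_channel_stack",
    "generate_predation_scene",
    "generate_trajectory",
    "odor_field",
    "tetrapod_wave_phases",
    "gallop_phases",
]


@dataclass
class GroundTruth:
    """Truth emitted next to each synthetic dataset."""

    swing_intervals: dict[str, list[tuple[int, int]]] | None = None  # frames, [on, off)
    drr0: np.ndarray | None = None  # true ΔR/R0 per frame
    contact_intervals: list[tuple[float, float]] | None = None  # seconds
    trajectory: "Trajectory | None" = None
    extras: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """A timestamped 2-D path in laboratory mm coordinates."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated (x, y) at time ``t``."""
        return np.stack(
            [np.interp(t, self.time, self.x), np.interp(t, self.time, self.y)], axis=-1
        )


# ---------------------------------------------------------------------------
# gait pose generator
# ---------------------------------------------------------------------------

def tetrapod_wave_phases(n_pairs: int = 4) -> np.ndarray:
    """Per-leg phase offsets of a posterior-to-anterior stance wave.

    Left and right legs of a pair are in antiphase; successive pairs are
    shifted by a quarter cycle from posterior to anterior, the coordination
    described for tetrapod-like walking.  Order: pair 1 (anterior) left,
    right, ..., pair n (posterior) left, right.
    """
    offs = []
    for i in range(n_pairs):
        base = ((n_pairs - 1 - i) * 0.25) % 1.0
        offs += [base, (base + 0.5) % 1.0]
    return np.array(offs)


def gallop_phases(n_pairs: int = 4) -> np.ndarray:
    """Phase offsets with left/right pairs synchronized (gallop-like)."""
    offs = []
    for i in range(n_pairs):
        base = ((n_pairs - 1 - i) * 0.25) % 1.0
        offs += [base, base]
    return np.array(offs)


@dataclass
class GaitParams:
    """Parameters of the synthetic walker.

    Defaults describe a tardigrade-scale animal: ~250 µm body, eight legs in
    four pairs, a 2 s stride at duty factor 0.6, walking at 100 µm/s and
    imaged at 30 Hz.  The noise defaults (1.6 µm per-frame jitter plus 5 %
    low-confidence dropouts mislocalized by ~12 µm) combine to an overall
    localization RMSE of ~3.1 µm, the error scale of a trained pose network
    on this kind of footage.
    """

    n_legs: int = 8  # as 4 pairs
    cycle_period: float = 2.0  # s
    duty_factor: float = 0.6
    phase_offsets: np.ndarray | None = None  # per leg, fraction of cycle
    swing_amplitude: float = 50.0  # µm along the body axis
    body_speed: float = 100.0  # µm/s
    body_length: float = 250.0  # µm
    turn_times: Sequence[tuple[float, float]] = ()  # (time s, angle deg)
    turn_duration: float = 0.5  # s over which a turn is executed
    noise_sd: float = 1.6  # µm, per-frame localization jitter
    dropout_rate: float = 0.05  # fraction of frames with likelihood < 0.7
    dropout_error: float = 12.0  # µm mislocalization of a dropped detection
    frame_rate: float = 30.0  # Hz
    duration: float = 30.0  # s
    pixel_size: float = 0.57  # µm/px (4.1x configuration)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ParameterError("duty_factor must lie in (0, 1)")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.n_legs % 2:
            raise ParameterError("n_legs must be even (legs come in pairs)")
        if self.phase_offsets is None:
            self.phase_offsets = tetrapod_wave_phases(self.n_legs // 2)
        self.phase_offsets = np.asarray(self.phase_offsets, dtype=float) % 1.0
        if len(self.phase_offsets) != self.n_legs:
            raise ParameterError("phase_offsets must have one entry per leg")


def _swing_displacement(phase: np.ndarray, duty: float, amplitude: float) -> np.ndarray:
    """Leg protraction displacement over one cycle.

    The swing (protraction) occupies the first ``1 - duty`` of the cycle with
    a quarter-sine profile — protraction speed is maximal at swing onset and
    decelerates to zero at the transition to stance — followed by a linear
    return (retraction) during stance.  With this waveform the peak of the
    first derivative marks the swing onset and the trough of the second
    derivative marks the offset, matching the swing detector's definitions.
    """
    swing_frac = 1.0 - duty
    out = np.empty_like(phase)
    in_swing = phase < swing_frac
    u = phase[in_swing] / swing_frac
    out[in_swing] = amplitude * np.sin(0.5 * np.pi * u)
    v = (phase[~in_swing] - swing_frac) / duty
    out[~in_swing] = amplitude * (1.0 - v)
    return out


def _heading(params: GaitParams, t: np.ndarray) -> np.ndarray:
    theta = np.zeros_like(t)
    for t_turn, angle_deg in params.turn_times:
        ramp = np.clip((t - t_turn) / params.turn_duration, 0.0, 1.0)
        theta = theta + np.deg2rad(angle_deg) * ramp
    return theta


def generate_gait_pose(params: GaitParams) -> tuple[PoseTrack, GroundTruth]:
    """Synthesize a walking pose track with known swing intervals.

    Returns a :class:`~btk.io_core.PoseTrack` in camera pixels (parts:
    ``front``, ``leg{i}_{left,right}`` anterior to posterior, ``rear``) and a
    :class:`GroundTruth` whose ``swing_intervals`` hold the true per-leg
    ``[onset, offset)`` frames, with the clean protraction series and center
    of mass in ``extras``.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration * params.frame_rate))
    t = np.arange(n_frames) / params.frame_rate
    n_pairs = params.n_legs // 2

    theta = _heading(params, t)
    # COM path: integrate speed along heading
    dt = 1.0 / params.frame_rate
    vx = params.body_speed * np.cos(theta)
    vy = params.body_speed * np.sin(theta)
    com_x = np.concatenate([[0.0], np.cumsum(vx[:-1] * dt)])
    com_y = np.concatenate([[0.0], np.cumsum(vy[:-1] * dt)])
    ux, uy = np.cos(theta), np.sin(theta)  # body axis unit vector (toward front)
    nx, ny = -uy, ux  # leftward normal

    L = params.body_length
    front_ap = 0.0
    rear_ap = L
    # leg attachment points along the body, anterior to posterior
    base_ap = np.linspace(0.22 * L, 0.85 * L, n_pairs)
    lateral = np.where(np.arange(n_pairs) < n_pairs - 1, 0.14 * L, 0.08 * L)

    parts: list[str] = ["front"]
    ap0: list[float] = [front_ap]
    lat: list[float] = [0.0]
    leg_names: list[str] = []
    for i in range(n_pairs):
        for side, sgn in (("left", +1.0), ("right", -1.0)):
            name = f"leg{i + 1}_{side}"
            parts.append(name)
            leg_names.append(name)
            ap0.append(base_ap[i])
            lat.append(sgn * lateral[i])
    parts.append("rear")
    ap0.append(rear_ap)
    lat.append(0.0)

    swing_frac = 1.0 - params.duty_factor
    phases = {}
    ap_clean = {}  # anterior-posterior distance from the front anchor, µm
    swing_truth: dict[str, list[tuple[int, int]]] = {}
    for j, name in enumerate(leg_names):
        phase = (t / params.cycle_period + params.phase_offsets[j]) % 1.0
        phases[name] = phase
        disp = _swing_displacement(phase, params.duty_factor, params.swing_amplitude)
        # protraction moves the foot toward the head: distance from front shrinks
        ap_clean[name] = ap0[1 + j] - disp
        if params.swing_amplitude > 0:
            cyc = np.floor(t / params.cycle_period + params.phase_offsets[j])
            onsets = np.flatnonzero(np.diff(cyc) > 0) + 1  # phase wraps to 0
            offs: list[tuple[int, int]] = []
            for on in onsets:
                # offset: first frame at/after onset whose phase reaches stance
                rel = phases[name][on:]
                k = np.flatnonzero(rel >= swing_frac)
                if k.size:
                    offs.append((int(on), int(on + k[0])))
            swing_truth[name] = offs
        else:
            swing_truth[name] = []

    n_parts = len(parts)
    x = np.empty((n_frames, n_parts))
    y = np.empty((n_frames, n_parts))
    for k, name in enumerate(parts):
        a = ap_clean[name] if name in ap_clean else np.full(n_frames, ap0[k])
        xx = com_x + (L / 2 - a) * ux + lat[k] * nx
        yy = com_y + (L / 2 - a) * uy + lat[k] * ny
        x[:, k], y[:, k] = xx, yy

    x += rng.normal(0.0, params.noise_sd, x.shape)
    y += rng.normal(0.0, params.noise_sd, y.shape)
    likelihood = np.clip(rng.normal(0.98, 0.01, x.shape), 0.0, 1.0)
    if params.dropout_rate > 0:
        drop = rng.random(x.shape) < params.dropout_rate
        likelihood[drop] = rng.uniform(0.05, 0.65, int(drop.sum()))
        x[drop] += rng.normal(0.0, params.dropout_error, int(drop.sum()))
        y[drop] += rng.normal(0.0, params.dropout_error, int(drop.sum()))

    margin = 2.0 * L
    track = PoseTrack(
        frame_index=np.arange(n_frames),
        time=t,
        parts=tuple(parts),
        x=(x + margin) / params.pixel_size,
        y=(y + margin) / params.pixel_size,
        likelihood=likelihood,
        pixel_size=params.pixel_size,
    )
    protraction = {name: params.body_length - ap for name, ap in ap_clean.items()}
    truth = GroundTruth(
        swing_intervals=swing_truth,
        trajectory=Trajectory(t, com_x / 1000.0, com_y / 1000.0),
        extras={
            "protraction_um": protraction,
            "ap_from_front_um": ap_clean,
            "leg_names": leg_names,
            "heading_rad": theta,
        },
    )
    return track, truth


# ---------------------------------------------------------------------------
# dual-channel fluorescence scene
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Dual-channel recording parameters.

    Defaults emulate a single labeled neuron followed by the tracker: a
    Gaussian-profile emitter wandering slowly in the field of view, imaged in
    a bright reference channel and a transient-carrying signal channel.  The
    stimulation-protocol default (five 1 s stimuli, 30 s apart, after a 30 s
    pre-period) matches a touch-response experiment.
    """

    n_frames: int = 600
    shape: tuple[int, int] = (48, 48)
    frame_rate: float = 20.0  # Hz
    emitter_sigma: float = 2.5  # px
    sig_amp: float = 400.0  # photons/frame at peak, green
    ref_amp: float = 600.0  # photons/frame at peak, red
    transient_times: Sequence[float] = ()  # s; () = transient-free scene
    transient_amp: float = 1.5  # fractional ΔF on the green channel
    transient_tau_on: float = 0.15  # s
    transient_tau_off: float = 1.2  # s
    artifact_amplitude: float = 0.0  # shared multiplicative artifact, CV scale
    artifact_timescale: float = 0.5  # s
    background: float = 100.0  # photons/frame/px
    bleach_tau: float = math.inf  # s
    read_noise_sd: float = 2.0  # counts
    wander_sd: float = 1.0  # px/s emitter drift
    pixel_size: float = 0.57  # µm/px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transient_amp < 0 or self.artifact_amplitude < 0:
            raise ParameterError("amplitudes must be nonnegative")
        if self.bleach_tau <= 0:
            raise ParameterError("bleach_tau must be positive")

    @classmethod
    def touch_protocol(cls, **kw) -> "SceneParams":
        """Scene with five 1 s stimuli at 30 s intervals after a 30 s pre-period."""
        onsets = 30.0 + 31.0 * np.arange(5)
        defaults = dict(n_frames=int(200 * 20), transient_times=tuple(onsets))
        defaults.update(kw)
        return cls(**defaults)


def _transient_kernel(t: np.ndarray, onsets: Sequence[float], tau_on: float, tau_off: float) -> np.ndarray:
    k = np.zeros_like(t)
    for t0 in onsets:
        dt = t - t0
        m = dt >= 0
        k[m] += (1.0 - np.exp(-dt[m] / tau_on)) * np.exp(-dt[m] / tau_off)
    return k


def generate_dual_channel_stack(
    params: SceneParams,
) -> tuple[tuple[ImageStack, ImageStack], GroundTruth]:
    """Render a (signal, reference) stack pair with known ΔR/R0.

    A shared multiplicative artifact scales the emitter in both channels
    identically (so it cancels in the channel ratio); calcium transients
    scale the green emitter only; photobleaching decays both; shot noise is
    Poisson and read noise Gaussian.
    """
    rng = np.random.default_rng(params.seed)
    nt = params.n_frames
    h, w = params.shape
    t = np.arange(nt) / params.frame_rate

    # emitter path: smoothed random wander around the FOV center
    steps = rng.normal(0.0, params.wander_sd / params.frame_rate, (nt, 2))
    path = np.cumsum(steps, axis=0)
    path = gaussian_filter1d(path, sigma=max(params.frame_rate * 0.25, 1.0), axis=0)
    path += np.array([h / 2.0, w / 2.0])
    lim = 3.0 * params.emitter_sigma
    path[:, 0] = np.clip(path[:, 0], lim, h - 1 - lim)
    path[:, 1] = np.clip(path[:, 1], lim, w - 1 - lim)

    if params.artifact_amplitude > 0:
        z = rng.normal(0.0, 1.0, nt)
        z = gaussian_filter1d(z, sigma=max(params.artifact_timescale * params.frame_rate, 1.0))
        sd = z.std()
        if sd > 0:
            z /= sd
        # lognormal: multiplicative focus/motion artifacts are strictly
        # positive with CV ~ amplitude
        artifact = np.exp(params.artifact_amplitude * z - params.artifact_amplitude**2 / 2.0)
    else:
        artifact = np.ones(nt)

    bleach = np.exp(-t / params.bleach_tau)
    trans = 1.0 + params.transient_amp * _transient_kernel(
        t, params.transient_times, params.transient_tau_on, params.transient_tau_off
    )

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    two_s2 = 2.0 * params.emitter_sigma**2
    spot = np.exp(
        -((rows[None] - path[:, 0, None, None]) ** 2 + (cols[None] - path[:, 1, None, None]) ** 2)
        / two_s2
    )
    gain = artifact * bleach
    exp_sig = params.background + (params.sig_amp * gain * trans)[:, None, None] * spot
    exp_ref = params.background + (params.ref_amp * gain)[:, None, None] * spot

    def noisy(expected: np.ndarray) -> np.ndarray:
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, params.read_noise_sd, counts.shape)
        return np.clip(counts, 0.0, None)

    meta = dict(
        channel_layout="single",
        exposure_ms=1000.0 / params.frame_rate,
        pixel_size=params.pixel_size,
        frame_rate=params.frame_rate,
    )
    sig = ImageStack(noisy(exp_sig), **meta)
    ref = ImageStack(noisy(exp_ref), **meta)

    drr0 = (trans - trans.mean()) / trans.mean()
    truth = GroundTruth(
        drr0=drr0,
        trajectory=Trajectory(t, path[:, 1] * params.pixel_size / 1000.0, path[:, 0] * params.pixel_size / 1000.0),
        extras={"artifact": artifact, "bleach": bleach, "path_rc": path},
    )
    return (sig, ref), truth


# ---------------------------------------------------------------------------
# predation scene
# ---------------------------------------------------------------------------

@dataclass
class PredationParams:
    """A predator-prey encounter at the mouth of the predator.

    Defaults emulate the dual-color predation assay: 30 fps imaging at the
    3.1x configuration (0.75 µm/px), a bite onset late enough that the
    −15..−5 s baseline window exists, and a prey-fluorescence blob appearing
    inside the mouth region during contact.
    """

    duration: float = 36.0  # s
    frame_rate: float = 30.0  # Hz
    shape: tuple[int, int] = (56, 56)
    pixel_size: float = 0.75  # µm/px (3.1x configuration)
    bite_onset: float | None = 18.0  # s; None = no-contact scene
    bite_duration: float = 4.0  # s of biting before feeding
    contact_duration: float = 15.0  # s of prey contact from bite onset
    prey_amp: float = 300.0  # photons above background at blob peak
    prey_sigma: float = 6.0  # px
    background: float = 100.0  # photons
    read_noise_sd: float = 2.0
    centerline_points: int = 20
    seed: int = 0


def generate_predation_scene(
    params: PredationParams,
) -> tuple[np.ndarray, ImageStack, Ethogram, GroundTruth]:
    """Render a predation encounter with known contact intervals.

    Returns ``(centerlines, green_stack, ethogram, truth)`` where
    ``centerlines`` has shape ``(n_frames, n_points, 2)`` in (row, col)
    pixels, ordered anterior-first.  Prey fluorescence appears within the
    predator's mouth region only during the true contact interval.
    """
    rng = np.random.default_rng(params.seed)
    nt = int(round(params.duration * params.frame_rate))
    h, w = params.shape
    t = np.arange(nt) / params.frame_rate

    # predator head near FOV center, slight jitter; centerline extends posteriorly
    anterior = np.array([h / 2.0, w / 2.0]) + gaussian_filter1d(
        rng.normal(0.0, 0.6, (nt, 2)), sigma=params.frame_rate / 3.0, axis=0
    )
    s = np.linspace(0.0, 1.0, params.centerline_points)
    body_len_px = 0.45 * min(h, w)
    direction = np.array([0.6, 0.8])
    curve = 6.0 * np.sin(np.pi * s)  # gentle pharyngeal curvature
    normal = np.array([-direction[1], direction[0]])
    centerlines = (
        anterior[:, None, :]
        + s[None, :, None] * body_len_px * direction[None, None, :]
        + curve[None, :, None] * normal[None, None, :]
    )

    if params.bite_onset is not None:
        contact = [(params.bite_onset, min(params.bite_onset + params.contact_duration, params.duration))]
    else:
        contact = []

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    expected = np.full((nt, h, w), params.background, dtype=float)
    for t0, t1 in contact:
        frames = (t >= t0) & (t < t1)
        # prey blob sits just anterior of the mouth, flickering as prey struggles
        flicker = 0.75 + 0.25 * np.abs(np.sin(2.0 * np.pi * 1.3 * t[frames]))
        d2 = (rows[None] - anterior[frames, 0, None, None]) ** 2 + (
            cols[None] - anterior[frames, 1, None, None]
        ) ** 2
        expected[frames] += (params.prey_amp * flicker)[:, None, None] * np.exp(
            -d2 / (2.0 * params.prey_sigma**2)
        )

    counts = rng.poisson(expected).astype(float)
    counts += rng.normal(0.0, params.read_noise_sd, counts.shape)
    stack = ImageStack(
        np.clip(counts, 0.0, None),
        channel_layout="single",
        exposure_ms=1000.0 / params.frame_rate,
        pixel_size=params.pixel_size,
        frame_rate=params.frame_rate,
    )

    state = np.full(nt, "exploration", dtype=object)
    if params.bite_onset is not None:
        state[(t >= params.bite_onset) & (t < params.bite_onset + params.bite_duration)] = "predatory_biting"
        state[t >= params.bite_onset + params.bite_duration] = "predatory_feeding"
    velocity = np.where(state == "exploration", 90.0, 25.0) + rng.normal(0.0, 5.0, nt)
    pump = np.where(state == "predatory_feeding", 3.5, 2.0) + rng.normal(0.0, 0.2, nt)
    eth = Ethogram(time=t, state=state, velocity=velocity, pump_rate=pump)

    truth = GroundTruth(contact_intervals=contact, extras={"anterior_rc": anterior})
    return centerlines, stack, eth, truth


# ---------------------------------------------------------------------------
# trajectories and odor field
# ---------------------------------------------------------------------------

def generate_trajectory(
    speed_profile: float | Sequence[float] | Callable[[np.ndarray], np.ndarray],
    turn_rate: float,
    duration: float,
    seed: int = 0,
    dt: float = 0.02,
    start_xy: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Correlated random walk in mm.

    ``speed_profile`` is a constant (mm/s), a per-sample sequence, or a
    callable of time; ``turn_rate`` is the standard deviation of the heading
    rate in rad/s (0 gives a straight path).  The instantaneous speed equals
    the profile exactly, so its maximum is the path's maximum speed.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    if callable(speed_profile):
        speed = np.asarray(speed_profile(t), dtype=float)
    else:
        speed = np.broadcast_to(np.asarray(speed_profile, dtype=float), (n,)).copy()
    if np.any(speed < 0):
        raise ParameterError("speeds must be nonnegative")
    dtheta = rng.normal(0.0, turn_rate * math.sqrt(dt), n)
    theta = np.cumsum(dtheta) - dtheta[0]
    x = start_xy[0] + np.concatenate([[0.0], np.cumsum(speed[:-1] * np.cos(theta[:-1]) * dt)])
    y = start_xy[1] + np.concatenate([[0.0], np.cumsum(speed[:-1] * np.sin(theta[:-1]) * dt)])
    return Trajectory(t, x, y)


def odor_field(
    source_xy: tuple[float, float],
    amount: float,
    diffusivity: float,
    t: float,
    query_points: np.ndarray,
) -> np.ndarray:
    """2-D instantaneous point-source diffusion kernel.

    ``C(r, t) = amount / (4 π D t) · exp(-r² / (4 D t))`` with ``D`` in
    mm²/s, positions in mm.  Illustrative of a freshly deposited odor drop;
    the true source strength and boundary conditions of a real assay are
    experiment-specific.
    """
    if t <= 0:
        raise ParameterError("t must be positive")
    if diffusivity <= 0:
        raise ParameterError("diffusivity must be positive")
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    r2 = (q[:, 0] - source_xy[0]) ** 2 + (q[:, 1] - source_xy[1]) ** 2
    c = amount / (4.0 * math.pi * diffusivity * t) * np.exp(-r2 / (4.0 * diffusivity * t))
    return c if np.asarray(query_points).ndim > 1 else c[0]
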