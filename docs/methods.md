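# Methods

This note documents the models, conventions and numerical choices behind
`btk`, in the spirit of a methods supplement: what each procedure assumes,
which knobs matter, and what the synthetic validation data do and do not
show about real recordings.

## Coordinate conventions

Pixel coordinates are 0-based with x along image columns (rightward) and y
along rows (downward). The laboratory frame is in mm with the same axis
orientation. `io_core.merge_with_stage` joins each camera frame to the
nearest-in-time stage sample (tolerance: half a frame period) and maps

    lab_x = stage_x + (x − fov_center_x) · pixel_size / 1000,

flagging frames whose stage sample was moving so downstream analyses can
discard them, mirroring the tracker's own policy of ignoring frames
acquired during stage motion.

## Ratiometric calcium signals

The extraction chain is: percentile background subtraction (the pooled
median of every 100th frame), Gaussian blur (σ = 0.3 px, interpreted as
pixels) followed by Otsu thresholding and largest-connected-component
selection, within-mask means per channel, then

    R = (F_sig / (F̄_sig + 1)) / (F_ref / (F̄_ref + 1)),    ΔR/R0 = (R − R̄) / R̄.

The "+1" pedestal in the means is implemented literally as published; it is
ambiguous whether it reflects a deliberate regularizer, so
`pedestal="off"` provides the conventional F/F̄ form. With the pedestal
off, a per-frame artifact a(t) multiplying both channels cancels exactly in
the instantaneous ratio; the window means only contribute a constant
factor, which ΔR/R0 removes. With the pedestal on, cancellation is exact up
to the pedestal's O(1/F̄) effect. Both modes are tested.

Window choice: F̄ and R̄ default to the whole trace; a prestimulus-window
option exists because the original convention is unstated.

Kymograph motion correction regresses the green channel on the red one per
body location: α(L) = Σ_t G·R / Σ_t R² (the closed-form least-squares
solution), F_corr = (G − αR) − ⟨G − αR⟩. The closed form is verified
against a brute-force grid minimizer in the tests.

Statistics: stimulus repeats are aligned at onset; the paired t-test
compares the −10..0 s prestimulus mean with the 0..1 s response mean. A
zero-variance difference returns p = 1 with a warning (the statistic is
undefined and the data show no effect). Repeats are optionally split by
reversal events within 2 s of onset, and the reversal effect is tested with
a random-intercept linear mixed model (statsmodels `MixedLM`; the
contribution here is the model contract, not the solver) using a Wald
z-test on the fixed effect.

Photobleaching is summarized as `1 − mean(last 5 %)/mean(first 5 %)` plus a
fitted exponential τ. Note the 5 % windows center at ~2.5 % and ~97.5 % of
the recording, so for a pure exponential over duration T the reduction is
`1 − exp(−0.95·T/τ)`, slightly below the endpoint value — tests use this
window-exact form.

## Prey-contact quantification

The prey signal is a contrast statistic over a 34 µm circular mask at the
anterior end of the predator centerline: `(p95 − p5)/p5` with
linear-interpolation percentiles computed per frame (a rolling-window
variant is deliberately not used; the convention is fixed by a worked
example in the tests). Frames with p5 ≤ 0 are undefined and are dropped
from window means rather than zero-filled. Each track is normalized to the
mean signal between 15 and 5 s before its first biting frame; tracks whose
modal pre-onset state is biting or feeding are excluded (their contact
predates the alignment point), and the rise is tested with an upper-tailed
paired t-test over −15..−5 vs 0..15 s.

## Gait pipeline

Likelihood gating uses the 0.7 threshold; gated positions are linearly
interpolated in time (edges held), never dropped. The centerline runs
through the front point, the left/right midpoint of each leg pair
(anterior→posterior) and the rear point, resampled to N = 100 points
equally spaced in arc length (N is a resolution choice; the count in the
original procedure is unstated). Body parts are projected **continuously**
onto the centerline polyline — nearest-vertex assignment quantizes the
anterior-posterior (ap) position to the point spacing (2.5 µm at N = 100),
which destroys derivative-based event detection.

Swing detection operates on the protraction-positive series
(`body_length − ap`): an onset is a prominent maximum of the first
derivative (peak protraction speed) and its offset the subsequent trough of
the second derivative (maximum deceleration). Offsets are stored as
`trough + 1` in half-open `[onset, offset)` intervals: the trough is the
last swing frame, so duty = 1 − swing/stride is unbiased on clean data.
Derivative estimation has two modes:

* Savitzky–Golay derivative filters, window 5, order 3 (default): on
  noise-free series this is near-exact — events land within ±1 frame of
  ground truth and duty-factor recovery is exact to the frame.
* Gaussian-derivative filters (`smooth_sigma`), with the deepest-trough
  pairing and prominence 3×MAD (`NOISY_DETECTOR` preset): the robust choice
  at pose-estimation noise. Heavier smoothing shifts events by ~σ frames
  and noise creates shallow spurious troughs right after onsets; the
  deepest-trough pairing (a deliberate deviation from first-trough pairing)
  resists those. At the generator's default noise this preset reaches
  ~0.85 frame accuracy against ground truth — the same regime as the ~0.8
  accuracy reported for automatic-vs-manual comparison on real recordings.

Peak prominences adapt as k·MAD of the derivative with a 0.2·SD floor (on
clean gaits most derivative samples are identical and the MAD collapses to
zero).

Agreement metrics: per-frame swing/stance accuracy, precision on swing
frames, onset/offset deltas from nearest-event matching within ±5 frames,
Pearson r over matched event indices; across animals r is combined by the
Fisher-z transform (arctanh–mean–tanh) and p-values by Fisher's method
(χ² = −2Σln p, df = 2k).

Trajectory behaviors: speed from central differences of stage coordinates
(µm/s); reversals are heading changes > 150° within a 1 s window, turns
fall in the 60°–150° band (bands configurable; events adjacent to a
reversal are not double-counted as turns); odortaxis success requires
entering and remaining within 5 mm of the target within the 5-minute
horizon.

## Gait-cycle clustering

Cycles are delimited by consecutive swing onsets of a reference leg
(default: the first leg pair); within each cycle every analyzed leg's ap
series is min-max normalized and resampled to 15 timepoints. Similarity is
dependent multivariate DTW — one warping path shared across legs, Euclidean
local cost, classic O(nm) dynamic program — validated exactly against
exhaustive path enumeration for short sequences. The distance matrix is
embedded in 2-D with UMAP (`metric="precomputed"`, fixed seed), clustered
with Ward agglomerative clustering on the embedding, and scored by the
silhouette on the embedding coordinates (a DTW-space silhouette would also
be defensible; the embedding is used because clustering operates there).
Stability across embedding seeds is the mean pairwise label agreement under
optimal one-to-one cluster matching (Hungarian assignment on the
contingency table). Cluster representatives are both the pointwise mean and
a DBA barycenter initialized at that mean (keeping the best iterate, so the
barycenter's DTW objective never exceeds the mean's). Per-cluster
kinematics aggregate per-animal means and use one-way ANOVA with Tukey
pairwise comparisons.

## Optics and closed-loop tracking

Magnification: `M = f_TL/f_OBJ` for fixed-focal objectives and
`M_eff = (f_TL/f_design_TL)·M_nominal` for infinity-corrected commercial
objectives on a non-design tube lens. Both are homogeneous of degree zero
in the focal lengths.

The tracking simulator is a discrete-event loop on the camera frame clock:
measure the animal's offset from the FOV center, command a stage move at
the update cadence, apply a communication latency (default 25 ms), slew at
a capped speed (default 20 mm/s, no acceleration model — only the cap is
known), one command in flight with queue-replacement. Frames exposed during
stage motion are motion-blurred; a centroid measured on one is biased by
half the stage displacement during the exposure (the centroid of a streak
is its midpoint), which is why skipping those frames
(`skip_during_motion=True`, the default) lowers tracking error. Loss of the
animal (offset beyond half the FOV diagonal) is a recorded outcome, not an
exception. The displacement estimator in the simulator abstracts the real
detector; a threshold + largest-component intensity centroid is provided
for frames.

## Synthetic data: what it does and does not emulate

* **Gait**: eight legs in four pairs on a 250 µm body, 2 s stride, duty
  0.6, posterior→anterior stance wave with left/right antiphase
  (tetrapod-like) or synchronized pairs (gallop-like); swing is a
  quarter-sine protraction (speed maximal at onset, deceleration maximal at
  touchdown — making the derivative definitions of onset/offset
  unambiguous) and stance a linear return. Noise: 1.6 µm per-frame
  Gaussian jitter plus 5 % likelihood dropouts mislocalized by ~12 µm,
  which combine to ~3.1 µm overall RMSE — the test-set error scale of a
  trained pose network on such footage. Real kinematics are smoother and
  their errors temporally correlated; passing these tests shows the
  event definitions and pipeline plumbing are correct, not that the
  detector's accuracy numbers transfer verbatim to any real video.
* **Dual-channel scenes**: a Gaussian emitter wandering in the FOV; shared
  lognormal multiplicative artifact (strictly positive, CV ≈ amplitude);
  green-only transients (fast rise, ~1.2 s decay); exponential
  photobleaching on both channels; Poisson shot noise + Gaussian read
  noise. No optical PSF beyond the Gaussian spot, no channel
  misregistration, background not modulated by the artifact.
* **Predation scenes**: stationary predator head with a curved centerline,
  prey-fluorescence blob inside the mouth region only during the contact
  interval, ethogram exploration→biting→feeding, 30 fps at 0.75 µm/px
  (scaled to 10 fps in the replication-heavy power checks — a problem-size
  choice stated here once).
* **Trajectories**: correlated random walk with exact speed profile;
  odor field is a 2-D instantaneous point-source diffusion kernel
  C(r,t) = A/(4πDt)·exp(−r²/4Dt) with parameters exposed rather than
  asserted (the real assay's source strength and boundary conditions are
  experiment-specific).

Problem sizes in the default test run: 30 s gait recordings (≈14 strides ×
8 legs), 100 gait cycles for cluster recovery, 100 × 17-track predation
experiments, 1000/500 null simulations for the statistical calibrations,
3600-frame one-hour bleaching scenes at 1 fps.

## Known limitations

* The swing detector's accuracy under noise depends on the smoothing scale
  relative to the stride period; the defaults assume ≳30 frames per stride.
* DTW is quadratic per pair and pure NumPy; distance matrices beyond a few
  hundred cycles get slow.
* UMAP determinism holds per seed on a fixed platform; embeddings (and
  hence silhouettes) are not comparable across library versions.
* The mixed-model z-test is asymptotic; with very few animals its type-I
  error drifts above nominal.
* The tracking simulator has no acceleration model and no autofocus; it
  bounds what feedback latency and stage caps allow, not servo dynamics.
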