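# btk — behavioral tracking toolkit

`btk` is an analysis toolkit for recordings made on low-cost fluorescence
tracking microscopes: instruments that keep a freely moving small animal
(a nematode, a fly larva, a tardigrade) centered in the field of view by
moving the stage in closed loop while imaging in one or two spectral
channels. It is aimed at labs doing calcium imaging and quantitative
behavior in unrestrained animals, and it covers the post-acquisition side
of such experiments end to end:

* **Ratiometric calcium imaging.** From dual-channel image stacks
  (activity-dependent GCaMP plus an activity-independent mKate2/mCherry
  reference): percentile background subtraction, Gaussian-blur + Otsu
  neuron segmentation, within-mask traces, and the channel ratio

      R = (F_sig/(F̄_sig+1)) / (F_ref/(F̄_ref+1)),   ΔR/R0 = (R − R̄)/R̄,

  in which artifacts that multiply both channels (motion, focus,
  bleaching) cancel. Includes per-location kymograph motion correction
  (α(L) minimizing Σ(G−αR)²), stimulus-aligned paired statistics, a
  random-intercept mixed model for reversal effects, pharyngeal
  pump-event detection, and photobleaching summaries.
* **Gait kinematics.** DeepLabCut-style pose tables are likelihood-gated
  and interpolated, the body is straightened against a centerline built
  from the front/rear points and leg-pair midpoints, and leg swings are
  detected from the anterior-posterior position: onset at the peak of the
  first derivative, offset at the trough of the second. Duty factors,
  automatic-vs-manual agreement (frame accuracy, precision, Fisher-z
  combined Pearson r), and trajectory behaviors (speed, turns, reversals,
  odortaxis success) follow.
* **Gait-cycle clustering.** Cycles (15 resampled timepoints per leg) are
  compared with dependent multivariate dynamic time warping, embedded in
  2-D with UMAP, clustered agglomeratively, and summarized by silhouette,
  DTW barycenters, per-cluster kinematics (ANOVA + Tukey), and
  seed-to-seed stability.
* **Predator–prey contact.** A 34 µm mask at the predator's mouth, the
  percentile-contrast prey signal (p95 − p5)/p5, baseline normalization to
  −15..−5 s before bite onset, ethogram alignment with the pre-onset
  modal-state exclusion rule, and an upper-tailed paired test of the rise.
* **Optics and tracking.** Magnification arithmetic
  (M = f_TL/f_OBJ; M_eff = f_TL/f_design·M_nominal) and a discrete-event
  simulator of the stage feedback loop (update rate, command latency,
  stage speed cap, skipping of motion-blurred frames).
* **Synthetic data.** Every analysis has a paired generator
  (`btk.synthetic_data`) producing ground-truthed inputs — gait pose
  tables with known swing intervals, dual-channel scenes with known
  ΔR/R0, predation scenes with known contact intervals, trajectories and
  diffusion odor fields — so the full pipeline is testable without any
  recordings.

## Worked example

Recover the duty factor and gait structure of a synthetic walker:

```python
import numpy as np
from btk.synthetic_data import GaitParams, generate_gait_pose
from btk import gait_kinematics as gk

params = GaitParams(duty_factor=0.6, seed=1)        # 8 legs, 2 s stride, 30 fps
track, truth = generate_gait_pose(params)           # DeepLabCut-style pose + truth

cleaned, com = gk.preprocess_pose(track)            # likelihood-gate + interpolate
straight = gk.straighten_track(cleaned)             # body-centerline coordinates
legs = truth.extras["leg_names"]
duties, accs = [], []
for leg in legs:
    swings = gk.detect_swings(gk.swing_series(straight, leg),
                              params.frame_rate, **gk.NOISY_DETECTOR)
    duties.append(gk.duty_factor(swings))
    accs.append(gk.compare_annotations(swings, truth.swing_intervals[leg],
                                       len(track)).accuracy)
print(f"mean duty factor: {np.nanmean(duties):.2f}")
print(f"frame accuracy vs truth: {np.mean(accs):.2f}")
```

Output:

```
mean duty factor: 0.74
frame accuracy vs truth: 0.86
```

The frame accuracy of ~0.86 against ground truth is what the automatic
detector achieves at a realistic pose-estimation noise level (~3 µm RMSE);
under noise the derivative-based events bias the duty factor upward from
the true 0.6, which is why noise-free validation (where recovery is exact)
and noisy validation are tested separately. And the optics one-liner:

```python
>>> from btk.optics_tracking import magnification_fixed, magnification_nominal
>>> magnification_fixed(50, 16)        # 50 mm tube lens, 16 mm objective
3.125
>>> round(magnification_nominal(50, 180, 10), 2)   # Olympus 10x on a 50 mm tube lens
2.78
```

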