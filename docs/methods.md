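# Methods

## Problem and pipeline

`gaitwarp` evaluates how well a markerless, single-camera gait analysis
(2-D pose keypoints from a lateral view, 60 frames/s) agrees with optical
motion capture (3-D marker trajectories, 240 frames/s) for sagittal-plane
hip, knee and ankle angles during straight walking. The two systems are
asynchronous and run at different rates, so frame-by-frame comparison is
invalid; the pipeline therefore aligns the angle waveforms with dynamic time
warping (DTW) before scoring similarity and computing Bland–Altman
agreement.

Fixed stage order:

1. read keypoints / markers (image y flipped to y-up at ingestion);
2. confidence gate — keypoints with confidence < 0.45 become missing;
3. gap filling — interior missing runs of ≤ 12 frames at 60 frames/s
   (equivalently 0.2 s at other rates, rounded to the nearest frame) are
   linearly interpolated; longer runs exclude the affected joint rows;
   leading/trailing runs are trimmed, never extrapolated;
4. outlier replacement — Hampel rule on each coordinate (rolling median,
   window 11 frames, gate 3 × 1.4826 × rolling MAD with a small absolute
   floor so constant signals yield no false positives), flagged samples
   re-filled by linear interpolation;
5. low-pass filtering — 6 Hz Butterworth, order 4, zero-phase
   (forward–backward); gait's dominant content sits below 5 Hz;
6. optional pixel→metre scaling from the subject's known standing height
   (angles are scale invariant, so this only affects reported coordinates);
7. synchronisation — ground-contact events are prominent local minima of
   the cleaned left-ankle vertical trajectory (prominence ≥ 0.3 of the
   signal range, ≥ 0.4 s apart); both systems are cropped to start at their
   first event;
8. angle computation, DTW alignment, similarity, agreement statistics.

## Angle conventions

All angles are in degrees, y-up coordinates, walking direction inferred
from the net horizontal hip displacement (overridable):

- **hip** — signed angle between the downward vertical through the hip and
  the hip→knee vector; thigh advanced toward the walking direction
  (flexion) positive;
- **knee** — 180° minus the interior angle at the knee between thigh and
  shank lines; full extension 0°, bending positive; symmetric in swapping
  the hip and ankle points;
- **ankle** — 90° minus the interior angle between the shank line
  (heel→knee) and the foot line (heel→toe); dorsiflexion positive.

Hip and knee are translation/scale invariant; knee and ankle are also
rotation invariant (the hip is referenced to gravity-vertical by design).
3-D markers are projected onto the sagittal plane (mediolateral axis
dropped) and run through the same formulas.

## DTW and the similarity score

Local cost d(x_i, y_j) = |x_i − y_j|; cumulative cost
D(i,j) = d + min(D(i−1,j), D(i,j−1), D(i−1,j−1)); DTW distance = D(N,M).
The warping path is recovered by backtracking; ties prefer the diagonal
predecessor, then (i−1, j) — the recurrence does not determine this, so it
is fixed here for reproducibility (diagonal-first keeps paths short). The
raw distance grows with series length, so it is divided by the warping-path
step count before scoring:

    similarity = exp(−(D(N,M) / path_length) / σ),   σ = 10 °/step.

σ carries the same units as the normalised distance; the score lives in
(0, 1] and decreases strictly with distance. No Sakoe–Chiba band or slope
constraint is applied by default (one is available in config). Without
path-length normalisation, exp(−D/σ) underflows for any realistic trial
length; the raw distance is still reported alongside.

## Agreement statistics

Differences are markerless − reference, so positive bias means the
markerless system overestimates. Bias = mean difference; SD uses the n−1
denominator; 95 % limits of agreement = bias ± 1.96 SD (held as an exact
identity in every reported row). Pearson r accompanies each row, and a
two-tailed one-sample t-test checks zero bias at the Bonferroni-corrected
threshold 0.05/6 (three joints × two sides). Frame-level pairs are treated
as independent; no repeated-measures correction is applied — a known
inferential caveat when many frames come from few trials.

**Pairing choice.** By default, Bland–Altman pairs are taken along the DTW
warping path. This has a structural consequence worth knowing: DTW warps
time to match *values*, so a constant offset b between the systems is
partially absorbed by the alignment and the measured bias is attenuated
toward zero. A `pairing="grid"` mode therefore resamples the reference onto
the markerless time grid (after event synchronisation) and pairs frame by
frame; bias-recovery validation uses this mode, where injected offsets of
1–5° are recovered to within ~0.02°. When absolute bias matters, use grid
pairing; when shape similarity under temporal distortion matters, use the
DTW pairing.

## Synthetic gait generator

The generator provides exact ground truth for every stage. Joint waveforms
are two-harmonic Fourier series over the gait cycle whose coefficients were
least-squares fitted to coarse normative adult sagittal curves
(hip ≈ −11…31°, knee ≈ 2…59° with the stance/swing double bump,
ankle ≈ −12…13°). Defaults: cadence 0.9 cycles/s (1.1 s stride), 5 cycles,
walking speed 1.2 m/s, thigh/shank 0.42 m, foot 0.25 m, subject height
1.70 m, 500 px/m, sampled at 60 frames/s (markerless) and 240 frames/s
(reference). The right leg lags the left by half a cycle.

The skeleton projection composes the angle conventions above, so the angle
formulas invert it to machine precision; the heel is placed on the shank
line below the ankle, making the heel→knee shank proxy exact. Cycle phase
is shifted once so the left ankle point's height minimum falls on integer
phase — heel-strike truth times then coincide with the detector's
operational definition of ground contact by construction, and trials open
half a cycle early so no event sits on a boundary.

Corruption models pose-estimation error: isotropic Gaussian pixel jitter,
per-frame confidence dropouts below the 0.45 gate, bursty gaps (geometric
lengths, plus deterministically forceable gaps for tests), and a constant
angular bias injected by rigidly rotating the shank+foot about the knee —
which shifts measured knee flexion by exactly the requested amount while
leaving hip and ankle angles untouched, giving bias-recovery tests an
exact truth. All outputs are deterministic functions of (config, seed).

What the generator does *not* emulate: soft-tissue and clothing artifact,
perspective/parallax error, self-occlusion correlated with gait phase,
pathological gait, and differing anatomical joint-centre definitions
between systems. Passing tests therefore demonstrate correctness of the
computational chain under the stated noise model, not clinical accuracy on
real recordings.

## Numerical and scale choices

- Validation problem sizes: 4–9 gait cycles per trial (≈ 260–600 frames at
  60 frames/s), 50 seeded trials for end-to-end checks, 100 for event
  detection — small enough to run interactively, large enough for stable
  medians.
- The DTW cost matrix is O(N·M) memory and compiled with numba; trial-scale
  series (≈ 1300 × 330) align in milliseconds.
- Interpolated samples always lie within their flanking values; filtering
  refuses signals that still contain missing samples (contract, not
  warning).
- Angle samples outside a plausibility window of [−60°, 180°] after
  cleaning are masked and re-filled under the same gap bound.
- Coincident landmark points yield missing angle samples, never errors.

## Known limitations

- DTW-path Bland–Altman attenuates constant biases (see pairing above);
  the default mirrors the published procedure, the grid mode quantifies it.
- Rate-mismatch alignment is bounded by value discretisation: aligning the
  same motion sampled at 240 and 60 frames/s, every fine-rate sample must
  pair with some coarse-rate sample, and within one coarse interval the
  angle moves by mean |ω|/60 ≈ 1.3–2° at physiological angular velocities.
  The optimal path's mean step cost therefore floors at ≈ 0.2–0.5 °/step,
  i.e. noise-free similarity ≈ 0.95–0.98, not 1.0. This is a property of
  the score at these rates, not an implementation artifact.
- Frame-level significance tests ignore within-trial correlation.
- Multi-person association, video decoding and pose estimation itself are
  out of scope; the package consumes estimator output.
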