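# Methods

## The problem and the approach

Marker-based and markerless pose tracking of animals routinely loses
keypoints: occlusion, reflections and tracking failures leave gaps of a few
frames to several seconds, and the dropout pattern is strongly keypoint- and
dataset-dependent.  Downstream analyses that need contiguous trajectories
(gait features, behavioral embeddings) then discard data or fall back to
linear interpolation, which is exact only when the motion is locally linear.

`skelimpute` imputes these gaps by masked modeling.  Complete 60-frame
windows are cut from the recordings; during training, artificial gaps drawn
from the *empirical* missingness process are zero-filled in the input while
the untouched coordinates remain the target.  A sequence model (transformer
encoder, bidirectional GRU, or TCN) reconstructs the hidden cells; the loss
is evaluated on the masked cells only.  Because the gaps mimic the real
dropout process, the trained model can be applied to the native gaps of the
same dataset.  A probabilistic head turns the same network into a
heteroscedastic Gaussian regressor whose mean per-sample predicted deviation
("estimated error") serves as a confidence proxy for accepting or rejecting
imputations.

## Data model and preprocessing

A recording is a `T x K x D` array (`D` in {2, 3}) with a boolean
missingness mask.  Missing cells are NaN internally; zero-filling happens
only when assembling model inputs, because zero is a legitimate coordinate
value.  A keypoint-frame with any NaN axis is treated as wholly missing —
coordinates are triangulated jointly and a lone surviving axis is not
trustworthy.

Each window is normalized in two steps with exactly invertible transforms:

1. **View-invariant rotation.**  The window is translated by the barycenter
   of the observed keypoints in its middle frame and rotated about z so the
   middle-frame heading aligns with (x=1, y=0).  The heading is either the
   vector between a configured keypoint pair (e.g. tail to head) or the
   first principal axis of the middle-frame x-y cloud; a principal axis has
   no intrinsic sign, so the sign is fixed by making its largest-magnitude
   component positive.  A zero-length heading falls back to the identity
   rotation and is flagged.  No rotation is applied about the x or y axes.
2. **Per-sample min-max.**  Every axis is mapped to [-1, 1] using the
   observed cells of that window only.  A static axis maps to 0 and its
   constant is stored so the inverse is well defined.  Scaling is computed
   *before* artificial masking so the inserted gaps cannot leak into the
   ground-truth scale.

The inverse (un-scale, un-rotate, un-translate) reproduces inputs to
< 1e-9, so imputations made in normalized space are reported in original
units.

## The empirical missingness model

Three distributions summarize the dropout process: the probability that a
gap event hits keypoint k (proportional to per-keypoint event counts); the
gap-length distribution per keypoint; and the inter-gap spacing
distribution.  All are estimated by run-length encoding the real masks.
With no observed missingness they fall back to uniform (lengths over
[1, 58]).  Keypoints can be excluded (probability forced to 0), e.g.
near-rigid keypoints that never need imputation.

Sampling a training gap draws a keypoint, a length (truncated to [1, L-2]
and renormalized) and a start offset from the inter-gap distribution
truncated to the legal starts and renormalized, falling back to uniform when
degenerate.  The first and last frame of the masked keypoint always stay
observed — this caps gaps at 58 of 60 frames and keeps the
linear-interpolation baseline applicable to every artificial gap.  Gaps are
regenerated every epoch as augmentation.  Several keypoints can be masked
simultaneously (a fixed count or a uniform range per sample); overlapping
gaps on one keypoint merge.

**Switch augmentation** exchanges the input coordinates of two random
keypoints over a random sub-interval with probability 0.1 per training
sample; the target stays unswitched, so the model learns to detect and undo
identity swaps.  At evaluation time switches are applied with probability
0.5 to probe robustness.

## Architectures

All backbones receive the zero-filled coordinates with the binary mask as an
extra channel and output one value per coordinate (two with the
probabilistic head).

* **Transformer** (reference config: 4 layers, model dim 128, 8 heads,
  feed-forward dim equal to the model dim).  Each (frame, keypoint) pair is
  a token: the keypoint's `D+1` values pass through one linear projection
  shared across keypoints, and learned lookup-table embeddings of the time
  index, keypoint identity and mask bit are summed on top — the mask thus
  enters twice, concatenated and embedded.  Blocks are pre-norm (layer
  normalization before attention/FFN): with the short CPU-scale trainings
  this package targets, pre-norm keeps early gradients well scaled.  The
  time-embedding table is initialized sinusoidally (still learnable) so
  attention can express relative-time alignment from the first steps.
* **GRU** (reference: 3 bidirectional layers, hidden 512, no dropout,
  output linear layer).  The flattened pose per frame (K x (D+1) values)
  feeds the recurrence; forward and backward passes are concatenated.
* **TCN** (reference: 4 residual blocks, two dilated causal convolutions
  each, kernel 2, dilations 1/2/4/8, hidden 256, dropout 0.2, ReLU).

The probabilistic head doubles the output and maps the raw scale through a
softplus with floor 1e-4, so predicted deviations are strictly positive.
Latent vectors for downstream embedding/classification are the mean over
tokens (transformer) or time steps (GRU) of the last pre-head layer; the
TCN has no fixed-width pre-head representation and is unsupported there.

The networks and their training run on a compact reverse-mode automatic
differentiation engine over NumPy arrays (`skelimpute.nn.autodiff`),
single-threaded and bit-reproducible for a fixed seed; gradients of every
op are pinned by finite-difference tests.

## Training

L1 loss on masked cells for point models; Gaussian negative log-likelihood
(mean over masked coordinates of `0.5 log(2 pi sigma^2) + (x - mu)^2 /
(2 sigma^2)`) for probabilistic models.  Adam with the reference schedule
lr 1e-3 (1e-4 for the full-size GRU, which is unstable at higher rates)
decayed by 0.95 every 500 epochs for 1500 epochs, batches of at most 32.
Validation gaps are frozen once at the start (seeded) so checkpoint
selection tracks a stationary criterion — training gaps are regenerated
every epoch, but regenerating validation gaps would add selection noise.
Validation RMSE is computed in normalized space (monotone with
original-space error within a sample group and much cheaper); the
parameters of the epoch with the lowest validation RMSE are returned.
Reported test metrics are always computed in original units after inverse
transformation.

### Desk-scale presets

The bundled experiments are sized for a single CPU core:

| setting | value |
|---|---|
| dataset | 12 simulated recordings x 1000 frames at 60 Hz, split 70/15/15 by recording |
| samples | 60-frame windows, stride 30; 256 train / 32 validation |
| transformer | 2 layers, dim 32, 1 head, ff 32; 50 epochs, lr 5e-3, batch 8, gamma 0.7 every 8 epochs |
| GRU | 2 bidirectional layers, hidden 48; 40 epochs, lr 1e-3, batch 32, gamma 0.7 every 10 |
| gap regime | 1-3 simultaneously masked keypoints, uniform lengths 1-58 |

These sizes are the package's supported desk configuration; the reference
hyperparameters above remain the defaults of `ModelConfig`/`TrainConfig`.
Under this preset the trained GRU reaches roughly a 2.5x lower RMSE than
linear interpolation on held-out 30-58-frame gaps of the oscillatory
fixture, and the transformer roughly 1.5-1.8x — the exact numbers are
recomputed by `scripts/acceptance.py`.

## Evaluation metrics

All metrics are computed only on masked keypoint-frames; the normalizer `N`
counts masked (frame, keypoint) positions, not scalar coordinates:

* RMSE = sqrt(1/N * sum of squared coordinate errors per masked position),
* MPJPE = 1/N * sum of Euclidean distances (MPJPE <= RMSE always),
* PCK@th = fraction of masked positions within `th x max_dist`, with
  `max_dist` the dataset-wide maximum inter-keypoint distance within a
  frame (computed over all splits) and th = 0.01 by default.

Two per-sample descriptors summarize motion content: *movement* (mean
absolute frame-to-frame coordinate difference) and *periodicity* (largest
non-DC magnitude in the Fourier spectrum of any coordinate, scaled by 2/L so
a pure sinusoid of amplitude a scores a; the DC term is excluded because any
offset would otherwise dominate).

## Full-recording imputation

Native gaps are imputed by tiling windows centered on each gap (shifted at
recording edges).  A window is skipped when a keypoint's gap run exceeds
L-2 frames (no recursive forecasting of prohibitively long gaps), when more
keypoints are simultaneously missing than the regime the model was trained
for, or — for probabilistic models — when the estimated error (mean
predicted deviation over the window's masked cells, normalized units)
exceeds the acceptance threshold (default 0.1).  Accepted windows are
inverse-transformed and written into the recording; cells covered by
several accepted windows are averaged, inverse-variance weighted when
deviations are available, giving deterministic, smooth seams.  Observed
coordinates are never altered; unimputed cells remain flagged.

The linear-interpolation baseline fills each interior gap per keypoint and
axis; leading/trailing gaps without anchors on both sides stay missing.

## Step detection and kinematics

Locomotor steps are detected on the smoothed ankle speed (per-frame
displacement x fps, moving average over 0.1 s).  Speed peaks must pass a
minimum height of 20 units/s, prominence 21, and a width at half prominence
between 0.16 and 2 s.  The thresholds are in the trajectory's native units
per second (mm assumed for mouse-scale data) and are all parameters.  The
swing start is the strongest acceleration before the peak and the stop the
strongest deceleration after it; the search is bounded to 2 s, to the
neighboring peaks, and to the peak's own near-base extent so an adjacent
bump cannot capture the anchor.  Acceleration is the first difference of the
already-smoothed speed.  The two duration rules act on different
quantities: 0.16-2 s gates the peak width, while the 0.6 s minimum applies
to the final start-to-stop interval.  Steps whose ankle is not lower at
start and stop than the swing-interior average are discarded.  Stride
length is the path length of the ankle trajectory over the swing; swing
duration is the interval over fps.  Detection runs per contiguous
non-missing segment, so gaps that imputation could not fill keep splitting
segments and hiding steps.

## The synthetic fixtures and what they do (not) show

`synthetic.simulate_recording` emulates the statistical structure the
models exploit: a body center drifting with a smooth random-walk heading,
rigid body-frame offsets, coherent sinusoidal limb oscillations (one shared
gait phase per individual — keypoints are strongly correlated), optional
attraction of a second individual (two-animal regime), and additive
Gaussian jitter.  The mouse-like preset (8 keypoints: hips, knees, ankles,
back; 3D; 60 Hz; ~2 Hz gait) matches the shape of a floor-exploration
motion-capture dataset so configurations transfer; the two-fish preset has
3 keypoints per animal.  `inject_missingness` places gap events as a
renewal process with configurable rate and length distribution — gaps are
never truncated, so run-length re-estimation recovers the injected
distribution exactly in expectation.  `make_step_trace` builds ankle-like
traces from tapered-cosine speed bumps with construction-derived ground
truth for every bump, including bumps deliberately violating a detector
gate.

Passing on these fixtures shows that the machinery is correct — that
models learn cross-keypoint and temporal structure where it exists, that
uncertainty tracks difficulty, that gates reject what they should.  It does
not show performance on real tracking data, which has non-stationary
behavior, outliers, soft-tissue artifacts and missingness correlated with
posture; desk-scale models and sample counts are far below the reference
configuration.

## Numerical choices and edge cases

* Missing representation: NaN + explicit mask; zero-fill only at model
  input.
* By-time splits: floor for the train boundary and the cumulative
  validation boundary, remainder to test.
* Degenerate heading: identity rotation, flagged.  Static axis: mapped to
  0, constant restored on inversion.
* Gap lengths/starts outside the legal range: truncate the distribution and
  renormalize; uniform fallback when the truncated support is empty.
* Std parameterization: softplus with floor 1e-4.
* Adam default betas (0.9, 0.999), eps 1e-8; gradient clipping off by
  default but exposed.
* Weight init: fan-in uniform for linear/recurrent maps, N(0, 1/sqrt(dim))
  for embeddings, sinusoidal initialization of the transformer's time
  embedding; all from one explicit seeded generator.
* Periodicity excludes the DC bin; ties in peak finding resolve to the
  earliest frame (scipy convention).
* Model weights are float32; gradients accumulate in each tensor's own
  dtype, so the float64 finite-difference tests keep full precision.

## Known limitations

* No recursive forecasting: gaps longer than L-2 frames are never
  partially imputed.
* The inference tiler centers windows on gaps; a learned window-placement
  policy might do better near recording edges.
* Single-threaded NumPy training is orders of magnitude slower than a GPU
  framework; the desk presets compensate with small models and datasets.
* Detecting *real* identity switches in data is out of scope; the switch
  module only builds robustness to them.
* Dataset-specific loaders (beyond generic CSV/npz/pose-CSV) and camera
  calibration are out of scope.
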