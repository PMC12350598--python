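# Methods

`sceneprompt` implements an auto-promptable multimodel segmentation and
tracking pipeline for RGBD surgical video, together with the control
logic that decides *when* to re-initialize it. This note records the
models, the parameter choices, the numerical conventions, and what the
synthetic test bed does and does not establish.

## Pipeline model

Three perception roles cooperate (the package defines them as abstract
contracts; any real model can be plugged in behind them):

1. **Prompt generator** — maps an RGBD frame to a per-pixel foreground
   probability map (the role a fast fully-supervised RGBD segmenter
   plays in a live system).
2. **Promptable segmenter** — maps point prompts on a frame to a binary
   mask (the foundation-segmenter role; implementations may resize
   internally, but must return a mask at the frame resolution).
3. **Tracker** — initialized with a reference mask, propagates it
   through subsequent frames (the semi-supervised video-object-
   segmentation role).

At the start frame: pixels with probability strictly above 0.9 become
candidate prompt points; with `N` candidates and spacing factor
`f = 0.1`, the prompt spacing is `s = sqrt(N) / f`, and prompts are
every `ceil(s)`-th candidate in row-major order starting at the first.
This stride reading yields about `f*sqrt(N)` prompts spread through the
candidate region (10 prompts for a 100x100 region). A Euclidean-pitch
reading of the same spacing rule would place fewer than one point in
any region (the pitch exceeds the region diameter for every `N`), so
the stride interpretation is the one implemented. The stride origin is
fixed at element 0: prompt placement is fully deterministic.

Each later frame is propagated by the tracker; the resulting mask —
*before* any correction — feeds the scene monitor and the re-prompting
policy. A trigger re-runs prompt generation and segmentation on the
current frame and re-initializes the tracker with the fresh mask:
detection implies immediate correction, and that frame's output comes
from the segmenter. If re-prompting finds no candidate pixels, the
tracker's mask is kept, the failure is recorded, and the detector is
reset, so degenerate scenes (full occlusion, lighting collapse) cannot
cause trigger storms. An entirely empty tracker mask forces a
re-prompt attempt regardless of policy (`force_reprompt_on_empty`).

## Monitored scene parameters

Six per-frame streams, each with a validity flag:

| stream | definition | units |
|---|---|---|
| `area_pct` | 100 x mask pixels / image pixels | % |
| `consistency_iou` | IoU of consecutive masks | [0, 1] |
| `depth_mean_m`, `depth_std_m` | mean / population sd of depth inside the mask, zeros (invalid returns) excluded | m |
| `cam_trans_m` | Euclidean norm of the relative pose translation | m |
| `cam_rot_deg` | geodesic angle of the relative rotation | deg |

Conventions: IoU of two empty masks is 1 ("no change" — an all-empty
pair must not read as a consistency collapse); exactly one empty mask
gives 0. Consistency and camera streams are invalid on the first frame
after (re-)initialization. Depth statistics use the population
standard deviation. Camera motion is invariant under a common rigid
change of world frame (tested property). Mean and sd of depth are
monitored as two separate detector channels.

## Scene-aware re-prompting (CUSUM)

Per monitored parameter the detector keeps a tabular CUSUM against a
moving baseline. With `mu_t` and `sigma_t` the mean and sample standard
deviation of the `W = 5` most recent observations and
`dX_t = X_t - mu_t`:

    S_t+ = max(0, S_{t-1}+ + dX_t - k*sigma_t)
    S_t- = max(0, S_{t-1}- - dX_t - k*sigma_t)

A change is flagged when `S+ > T` or `S- > T` (strict), with
`T = alpha * sigma_t`. Defaults: `k = 0.5`, `alpha` is the
re-prompting sensitivity (sweep 2..10). Multiple channels combine by
OR; the first triggering channel in registration order is reported; a
trigger resets every channel (sums and windows), because re-prompting
restarts the monitored statistics.

Three definitional choices were genuinely open and were settled by
calibration on the detector's step-response task (sustained 50% level
shift in a stream with 1% relative noise; target: near-certain
detection within 5 frames, rare pre-shift false alarms):

- **Window includes the current observation.** Excluding `X_t` from its
  own baseline inflates `Var(dX_t)` by `(1 + 1/W)` and, at `W = 5`,
  empirically drives the pre-shift false-alarm rate close to 1 — the
  accumulated sums outrun the noisy threshold on almost every run.
  Including it gives `dX_t = (1 - 1/W)(X_t - mean(others))`, a shrunken
  but far better-behaved deviation.
- **Sample (ddof 1) standard deviation in the window.** The population
  estimate on five samples biases `sigma_t` — and with it both the
  slack `k*sigma_t` and the threshold `T` — low by ~15%, roughly
  doubling false alarms. (Depth statistics in the scene monitor are a
  *measurement*, not a noise estimate, and keep the population form.)
- **Warm-up.** The first `W` observations only fill the window; no
  trigger can occur before observation `W + 1`.

With these choices the detector reaches ~99% detection within 5 steps
with a ~5% pre-shift false-alarm rate over 200 seeded streams; both
rates are recomputed by the test suite and the acceptance script.

`sigma_t = 0` on a constant window would make `T = 0` and trigger on
floating-point jitter, so both the slack and the threshold use
`sigma_eff = max(sigma_t, 1e-6 * max(1, |mu_t|))`. A genuine level
shift against a near-constant baseline still fires immediately, since
`dX_t` then dwarfs any plausible threshold.

## Interval policies and timing

`R_n` re-prompts whenever `frames_since_prompt >= n`; `R_inf` never
re-prompts; `R_1` re-prompts every frame (and is bit-identical to
running prompt generation + segmentation independently per frame, a
tested equivalence). Per-frame cost in simulated mode is the sum of
the latencies of the stages that executed; defaults are the measured
single-GPU per-frame costs of the three reference models: prompt
generator 69.3 ms, segmenter 428.4 ms, tracker 84.1 ms. The tracker
cost is charged on every processed frame (initialization included);
prompt generation and segmentation only on frames where they ran.
`simulated_fps = 1000 * n_frames / total_ms`. Without a cost model the
pipeline records wall-clock per frame.

## Synthetic scene generator

The generator emulates the *structure* of intraoperative head-mounted
RGBD recordings, not their appearance: a deformable organ, transient
occlusions at nearer depth, bounded camera motion, and a global
lighting change, over ~600 frames at the 320x288 time-of-flight grid.

- **Organ**: an ellipse (default radii 95x75 px at center (160, 144),
  depth 0.5 m with a 5 cm dome) whose boundary radius is modulated by
  three sinusoidal harmonics (orders 2-4, relative amplitude 0.01
  baseline, +0.04 during explicit deformation periods, periods of
  60-120 frames). This gives smooth deformation with an analytic
  silhouette — consecutive static-period masks overlap with IoU > 0.97.
- **Occluders**: disks (radius 45-60 px) at 0.3 m sweeping linearly
  across the organ during occlusion periods; trajectories are drawn
  from the seed. Ground truth is the organ silhouette minus occluder
  silhouettes, and occluder depth is strictly nearer than the organ it
  covers (tested at every covered pixel).
- **Camera**: within camera-motion periods the pose sweeps a bounded
  sinusoidal path (translation amplitude 0.05 m, roll 5 deg), returning
  to rest at period boundaries so the trajectory is continuous; the
  silhouette shifts by the corresponding parallax (focal 250 px).
- **Default schedule** (`default_surgery_schedule`): five equal
  periods — static, camera motion, occlusion, camera motion +
  occlusion, lighting change — while the organ scale ramps so its image
  share runs from ~14% to ~35%, spanning the per-patient organ-
  visibility range seen clinically.
- **Noise**: Gaussian RGB noise (sd 3 gray levels), depth noise
  (sd 4 mm, clipped at 3 sd so layering cannot invert), 0.2% random
  time-of-flight dropout (depth 0 = invalid), depth quantized to
  integer millimeters. All randomness derives from the schedule seed;
  identical seeds give bit-identical datasets.

What the generator does *not* emulate: photorealistic tissue
appearance, specular highlights, smoke, non-rigid instrument shapes,
registration error between color and depth, or rolling-shutter
artifacts. Passing tests therefore establish the correctness of the
orchestration and control logic under controlled perception error —
not clinical segmentation accuracy.

## Mock backends

The mocks read ground truth (synthetic data only) and degrade it in
controlled, seeded ways; all randomness is keyed by (seed, frame
index), never call order, so identical frames give identical outputs
under any policy.

- **Oracle prompt generator**: probability 0.95 inside a jittered copy
  of the silhouette (random shift and grow/shrink up to 2 px by
  default), 0.05 outside, with a 5% chance of a spurious blob —
  emulating a fast but error-prone RGBD segmenter.
- **Oracle segmenter**: erodes or dilates the silhouette along its
  Euclidean distance transform to a per-frame target IoU drawn within
  ±0.03 of 0.85 (the selection is by area quantile, so the landed IoU
  is within ±0.05 of target including tie effects). Prompts outside
  the object add a small spurious component.
- **Drifting tracker**: translates its reference mask along a seeded,
  direction-biased drift whose displacement grows at `decay = 0.01` of
  the object's equivalent radius per frame, plus one-pixel boundary
  noise; frames where the true area jumps by >10% inject extra drift
  (occlusion sensitivity). Re-initialization restores the reference
  exactly. With decay 0 the tracker is an identity propagator.

Noiseless settings make every mock exact, so the full pipeline
reproduces ground truth frame-for-frame — the end-to-end identity test.

## Evaluation protocol

Per-frame IoU against ground truth; median reported first, mean ± sd
secondary; FPS from the cost model; re-prompt share = applied
re-prompts / processed frames. Each configuration is evaluated from
five start frames 25 frames apart and per-frame IoUs are pooled.
Strategies are compared with the two-sided Wilcoxon matched-pairs
signed-rank test on per-frame IoU pairs (zero differences dropped;
all-identical input is reported as degenerate with p = 1). Pairing at
the frame level is the synthetic analog of the clinical per-patient
pairing; frames within a video are serially correlated, so the
resulting p-values overstate independence and should be read as
effect-confirmation on this controlled bench, not as clinical
inference.

The standard sweep covers `R_inf`, `R_50..R_10` (step 10), `R_1`, and
scene-aware for alpha in {2, 4, 6, 8, 10} crossed with seven parameter
sets (each singleton plus size + consistency).

Problem sizes used by the shipped experiments: the trade-off study runs
the full 600-frame default scene over 10 seeds for the interval ladder
and 5 start frames for the strategy comparison; unit tests use 30-100
frame videos, many at a quarter-resolution grid (80x72), which is ample
to pin down mask-level arithmetic.

## Known limitations

- The cost model reproduces *orderings* (which strategy is faster),
  not absolute clinical frame rates, which depend on hardware and
  pipeline engineering outside this package's scope.
- CUSUM state builds on recent frames; a corrupted early segmentation
  biases the baseline until the next re-prompt (inherent to the
  method; mitigated but not removed by the full reset on trigger).
- The drifting tracker's error model (rigid drift + boundary noise) is
  a deliberate simplification; real trackers fail in structured ways
  (bleeding across contrast edges, identity switches) that the mocks
  do not imitate.
- Real-model adapters (actual networks behind the three contracts) are
  an extension point, deliberately not shipped.
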