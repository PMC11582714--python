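# Methods

This note documents the models and procedures implemented in `herdtrack`,
the parameters that matter, what the synthetic scenarios do and do not
emulate, and the design decisions taken where the design was genuinely
open.

## Motion model

Tracks follow a linear-Gaussian constant-velocity model over the 8-D state
`(x, y, γ, h, ẋ, ẏ, γ̇, ḣ)`: box center (px), aspect ratio (w/h,
dimensionless), height (px) and their per-frame velocities.  The frame step
is normalized to one frame; wall-clock time enters only the servo module.
Noise standard deviations scale with the box height so the filter is
invariant to object scale: per-step process std is `w_p·h` on positions and
`w_v·h` on velocities, measurement std `w_p·h`, with defaults `w_p = 1/20`,
`w_v = 1/160` (the convention of the appearance-based tracking literature;
the aspect-ratio channel uses small fixed stds of 1e-2/1e-5 process and
1e-1 measurement).  Initiation places the full prior mass at the detection
with zero velocity and inflated diagonal covariance (2× position, 10×
velocity).  Updates use a Cholesky solve; a singular innovation covariance
raises a numerical-failure error rather than silently regularizing.

## Optical-flow compensation

When a confirmed track matches no detection, sparse pyramidal Lucas–Kanade
flow predicts where its box moved between the previous and current frame:

* a 7×7 point grid is sampled in the central 70% of the last box;
* each point is tracked coarse-to-fine over a 3-level image pyramid with a
  15 px window, Gauss–Newton iterations capped at 15, convergence at
  0.03 px;
* a point is accepted only if the structure tensor's smaller eigenvalue
  (per pixel) exceeds 1e-3 — rejecting low-texture regions — **and** it
  passes a forward–backward consistency check at 1 px.  The raw LK
  residual alone is unreliable on noisy, texture-poor backgrounds.
* translation is the median point displacement; scale is the median
  pairwise-distance ratio, clipped to [0.5, 2]; the aspect ratio is held
  fixed.  Translation + isotropic scale is the subset of box motion that
  sparse flow recovers robustly.
* the prediction is invalid when fewer than half the points survive.

A valid flow box updates the Kalman filter as a pseudo-measurement with the
measurement std multiplied by 2 (flow is useful but less trustworthy than a
detector box).  A matched detection always takes priority; with neither,
the filter runs predict-only.

Three admissibility guards protect identity, because sparse flow tracks
*texture*, not *identity*:

1. the pseudo-measurement must fall inside the track's own Mahalanobis
   gate;
2. it is rejected when any other track's box overlaps the flow region
   (IOU > 0.15) — during crossings the visible texture belongs to the
   occluder, and following it drags the occluded track into an identity
   switch;
3. a track bridged by flow keeps age-1-style eligibility for the IOU
   fallback matcher on the next frame: the pseudo-updates legitimately
   tighten the covariance, and without the fallback the reappearing
   detection can be gated out, spawning a duplicate track.

Flow is computed only for tracks the association stage left unmatched;
matched tracks always use the detector box, so computing flow for them
would be pure waste.

## Association

Per frame: (1) detections below `t_d` are discarded (strict inequality,
"above the threshold"); (2) confirmed tracks compete for detections in a
matching cascade ordered by non-association age (1 first), each round
solving a gated minimum-cost assignment on the combined cost
`λ·d⁽¹⁾ + (1−λ)·d⁽²⁾`; (3) tentative tracks plus confirmed tracks that
just missed (age 1, or flow-bridged) get an IOU fallback round at gate 0.3.
Defaults: `λ = 0` (appearance-dominant cost, Mahalanobis as gate only),
Mahalanobis gate 9.4877 (χ², 4 dof, 0.95), appearance gate 0.2, gallery of
the last 100 matched features.  Gated entries carry a 1e5 sentinel for the
solver and are stripped from its output, so the gate is exact; the
deterministic solver plus index order makes tie-breaking reproducible.  If
detections arrive without appearance features the cascade falls back to a
motion-only cost with the appearance gate vacuous.

## Track lifecycle and low-confidence filtering

A new unassociated detection initiates a *tentative* track whose
confidence history is seeded with the initiating detection's confidence.
A tentative track is deleted the moment it misses a frame.  Once it has
accumulated `t_tentative = 3` matched-frame confidences, it is confirmed
**only if** their mean strictly exceeds `t_ave_d` (default 0.7); otherwise
it is deleted.  Setting `t_ave_d = 0` recovers the baseline tracker's
confirm-on-survival behavior exactly (pinned by a byte-identical
regression test).  Flow pseudo-updates append no confidence — flow has no
detector confidence — so the mean is taken over genuinely detected frames
only.  Confirmed tracks die when their non-association age exceeds
`max_age = 30`.  Reported output contains confirmed tracks that received a
measurement (detection or valid flow) in the current frame.

The point of the two-stage rule: running the detector at a low or zero
`t_d` avoids missing occluded animals, and the confirmation-time mean
confidence is what separates real-but-occluded targets (high-confidence
history) from persistent clutter (uniformly low confidence).

## Evaluation

CLEAR-MOT scoring matches ground truth to hypotheses per frame by IOU at a
0.5 threshold, previous-frame pairings persisting while still admissible
(the CLEAR continuity rule), the remainder by minimum-cost assignment.
FP = unmatched hypotheses, FN = unmatched ground truth, IDSw = covered
identity whose hypothesis id changed, FM = interruptions of an identity's
coverage strictly between matched frames (a trailing gap does not count);
`MOTA = 1 − (FN+FP+IDSw)/GT`; MOTP is the mean matched overlap (so 1.0 is
perfect localization).  MT counts identities covered in ≥ 80% of their
lifetime (80% exactly counts), ML those under 20% (20% exactly does not
count); both boundaries are pinned by tests since prose definitions of
these metrics are ambiguous at equality.

PR- variants rerun the tracker over a detection-confidence grid (default
0.0–0.9 in steps of 0.1), compute detection precision/recall and CLEAR
scores at each operating point, and average each metric along the PR curve
— a trapezoidal mean over recall, falling back to the arithmetic mean when
recall does not vary.  The trapezoid-over-recall rule is a protocol choice:
the metric family is defined by sweeping operating points, but no single
aggregation formula is canonical.

A false-positive *trajectory* (as opposed to a false-positive box) is a
confirmed track id whose reported boxes overlap ground truth (IOU ≥ 0.3)
in fewer than half its frames.

The annotation quality filter discards ground-truth objects with
truncation > 0.5 or occlusion > 0.5 and labels occlusion severity: none
(0), partial (up to one half), heavy (beyond one half).

## Visual servoing

Signals are measured from the confirmed tracks of the current frame
(pixels; `Δt` in seconds):

* `Sp_x` — sum of horizontal center offsets from the image center;
  `Sd_x` — sum of per-identity center changes since the previous frame;
  `Si_x` — accumulated `Sp_x`, reset whenever the tracked-id set changes
  and clamped to ±1000 (anti-windup: the summed error is not comparable
  across different herds-in-view).
* Height band (default 28–40 px): `Sp_y_h_b = Σ(h − h_max)` over too-tall
  boxes, `Sp_y_h_f = Σ(h_min − h)` over too-short boxes (both nonnegative
  magnitudes), `Sd_y_h = Σ ḣ`.  Optional area terms use
  `(A_ref − A)/A_ref`; they are disabled by default (`reference_area =
  None`) because the height band already encodes the distance objective
  and the two channels would fight.
* `Δh` — signed altitude distance to the nearest edge of the altitude band
  (default 10–14 m), zero inside: the vertical channel is deliberately a
  loose dead-band regulator.

The longitudinal law places the retreat sign on the too-tall band term and
the height-rate damping term (`ẏ = Kp_y·Sp_y_a + Kd_y·Sd_y_a −
Kp_y·Sp_y_h_b + b_f·Kp_y·Sp_y_h_f − Kd_y·Sd_y_h`): with the band terms
defined as magnitudes, a stable loop under the "+y forward, too-near
retreats" convention requires opposite signs on the near and far branches.
`b_f` (default 1) weights the approach branch.

Yaw misalignment is estimated from the two outermost tracked objects as
`ψ = atan2(h₁/std₁ − h₂/std₂, κ·|Δx|/W)`: the normalized height
difference is an inverse-range difference, and `κ = 2·tan(HFOV/2)·cos(tilt)`
(default √2 for a 90° field of view tilted down 45°) rescales the
width-normalized lateral separation onto the same inverse-range scale.
Without `κ` the estimate is biased by exactly that factor at the reference
range.  Swapping the two objects flips the sign; identical centers are a
geometry error.  The yaw-rate command is `Kp_ψ·ψ/Δt`.

Default gains (`Kp_x = 0.02`, `Ki_x = 2e-5`, `Kd_x = 0.02`, `Kp_y = 0.02`,
`Kd_y = 0.01`, `Kp_z = 0.5`, `Kp_ψ = 0.1`) were chosen for a smooth,
PD-dominant response at a 10 Hz control rate on the simulated plant: the
proportional lateral gain gives a ~2.5 s time constant at 15 m range, and
the integral term is a trim-level correction — larger integral gains
produce the textbook windup overshoot.  Commands are rotated to the world
frame by the heading (a planar rotation preserving horizontal speed).

## Synthetic scenarios

The generator emulates what the tracker and controller actually consume
from aerial herd footage:

* **Trajectories**: integrated heading processes (smoothed Gaussian
  turn-rate noise; constant heading; constant-curvature arcs; concentric
  arcs for the servo scenario) at 1–2.5 px/frame, with gentle steering
  toward the frame center near borders — animals turn, they do not bounce,
  and velocity kinks would confound the constant-velocity filter for
  artificial reasons.
* **Detections**: ground-truth boxes plus i.i.d. Gaussian coordinate noise
  (default 0.5 px), confidence uniform in 0.7–0.95 (reduced under partial
  occlusion); detections vanish during scheduled dropout runs (default
  3–5 frames) and when occlusion exceeds one half.
* **Clutter**: spurious detections spawn as a Poisson process and persist
  for a geometric lifetime (mean 6 frames) as a jittered stationary box
  with confidence uniform in 0.2–0.4 and its own feature vector.
  Persistence matters: repeated misdetections of rocks, shadows or dung
  patches are what actually confirms false trajectories in a baseline
  tracker — isolated single-frame false positives can never survive the
  confirmation window, so they would make the mean-confidence stage look
  trivially unnecessary.
* **Features**: a fixed unit vector per identity (dimension 16) plus
  Gaussian noise (std 0.1), renormalized.
* **Frames**: dark speckle-textured ellipses (grazing yaks are mostly
  black and gray from above) anchored to the box with subpixel bilinear
  placement so the texture genuinely translates and scales with the
  target; background noise is regenerated per frame so it is sensor noise,
  not trackable structure.
* **Plant**: a pinhole camera (90° HFOV, 45° down-tilt) on a kinematic
  vehicle whose velocity relaxes to the command with a first-order time
  constant (0.3 s) — the attitude loop is abstracted away, as it is
  handled by the autopilot in a real system.

All randomness flows from one root seed through named child streams, so
toggling clutter does not perturb trajectories; scenarios are reproducible
bit for bit.

What the scenarios do **not** emulate: detector-specific error structure
(correlated misses, double detections, localization bias), appearance
drift with pose and lighting, perspective footprint distortion, camera
motion blur and rolling shutter, and real flight dynamics beyond the
first-order lag.  Passing benchmarks here demonstrates the mechanisms —
flow bridging reduces fragmentation, mean-confidence filtering removes
false trajectories at no MOTA cost, the servo loop converges — not
field-level absolute scores.

## Benchmark conditions and problem sizes

The frozen dropout benchmark uses 2 targets, 300 frames at 256×192 px,
dropout runs of 3–5 frames at a 2% per-frame start rate, 20 seeds; the
clutter benchmark uses 2 targets, 200 frames, one clutter spawn per frame
at confidence ≤ 0.4, no dropouts, 20 seeds; the demo fixture is 3 targets
and 60 frames.  These sizes give stable aggregate counts (hundreds of
dropout/clutter events) while keeping a full run of the suite and the
acceptance script in the minutes range on one core.

## Known limitations

* Flow compensation assumes the target remains visible when the detector
  fails; during genuine full occlusion the ambiguity guard deliberately
  degrades to predict-only coasting.
* The scale channel of the flow prediction is crude (median distance
  ratio); γ is never updated by flow.
* The yaw estimator's calibration constant assumes targets near the
  reference range; far outside the height band the estimate is biased.
* PR- aggregation is one defensible protocol among several; absolute PR-
  values are comparable only within this implementation.
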