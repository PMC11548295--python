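# Methods

`anklestage` implements a decision pipeline for VR-aided ankle
rehabilitation after stroke: classify each training cycle into a
Brunnstrom motor-recovery stage (I–V) from wearable-sensor features, and
map the decided stage to virtual-scene control parameters. This note
documents the models, the synthetic data they are exercised on, the
numerical choices, and the limits of what the tests show.

## The decision problem

During a rehabilitation session a patient performs repeated ankle
training cycles inside one of three virtual scenes. Each cycle yields a
six-channel feature sequence sampled at 60 Hz: the ankle angle
trajectory, its angular velocity and jerk, a normalized assessment
score, and two scene-completion indicators (task completion count and
completion degree). A classifier maps fixed-length windows of this
sequence to a stage; cycle-level predictions are smoothed over a
five-cycle window (two cycles before and after the focal cycle) by
majority vote, ties broken toward the focal prediction. The decided
stage selects per-stage scene control parameters: three response
coefficients λX, λY, λZ (the per-axis gains that scale how strongly
real ankle rotation drives the virtual avatar) and the maximum obstacle
contact distance (collision tolerance, shrinking as the patient
recovers).

## Pose transformation

The ankle–foot pose is decomposed into three consecutive rotations
about x, y, z, each scaled by its response coefficient:

    A = (λX·RX(φ)) · (λY·RY(θ)) · (λZ·RZ(ψ))

The sign layout puts `sin` above `−sin` in each factor (the transpose of
some textbook conventions); it is preserved as the project's fixed
convention. λ scales the whole factor matrix, so
`A(λ) = (λX·λY·λZ)·A(1)` entry-wise and `det A = (λX·λY·λZ)³`; at unit
gains A is a proper rotation. Whether the gain belongs inside the pose
matrix or only in a downstream interaction term is ambiguous in
principle; the matrix form is implemented because it is the form the
transformation equations state. The default per-stage table (λ from 0.6
to 1.4 and contact distance from 5 to 1 scene units across stages I→V)
ships in `config/control_params.yaml`; values are the package's own
choice since no numeric table is published.

## Synthetic sessions

No public dataset exists for this task, so `synthetic_data` generates
sessions with the protocol's structure. Per stage a `StageProfile`
holds Gaussian distributions for the active range of motion (AROM),
voluntary angular speed, jerk level, assessment score, completion count
(Poisson) and completion degree. The packaged defaults
(`config/default_profiles.yaml`) are hand-chosen, well-separated and
clinically ordered: AROM 0.15→0.75 rad and score 0.15→0.90 increase
with stage, jerk 80→15 rad/s³ decreases (jerk is a roughness indicator,
so less recovered = rougher), and stage V moves at the nominal guidance
speed π/6 rad/s with a 2 s hold at peak flexion.

A cycle's angle trajectory is a raised-cosine ramp to a peak drawn from
the stage's AROM distribution (ramp duration = peak / sampled speed), a
2 s plateau, and a raised-cosine return — smooth, differentiable, with
non-trivial jerk. A 4 Hz tremor rides on the movement, its amplitude
set so that its third derivative matches the stage's jerk level
(amplitude = jerk / (2π·4)³), multiplied by the movement envelope so
rest stays quiet. Velocity and jerk channels are backward finite
differences of the angle channel divided by the 1/60 s timestep
(first and third order), mirroring what an IMU pipeline computes; the
velocity channel therefore integrates back to the angle channel
exactly. Score/completion channels are constant within a cycle.

What this emulates: per-stage separation of kinematic and score
features, imbalanced class counts, multi-scene assignment, smoothness
differences across stages. What it does not: real IMU noise spectra and
drift, inter-subject variability structure, compensatory movements,
correlated channel noise, or any physiological model. Passing
classifier tests therefore demonstrate that the pipeline is correct and
learnable on separable data — not clinical-grade accuracy.

## Augmentation

Cycles are cut into 50-timestep windows. The stride grid
{50, 35, 25, 15} corresponds to 100/70/50/30 % of the window; 25 (50 %)
is the default, the best-performing setting. The window count follows
`floor((T − W)/S) + 1`.

SMOTE balances minority stages on the *training split only* (the split
is cycle-level and happens before augmentation, so synthetic windows
never leak into validation or test). For each synthetic sample, a
minority window A is drawn uniformly, its k = 5 nearest minority
neighbours are found by Euclidean distance on the flattened raw window
(no normalization — distances are taken on raw features), one neighbour
B is drawn uniformly, and C = A + λ(B − A) with λ ~ U[0, 1]. Neighbour
ties break to the lowest index for determinism. The upsampling rate
(percent of the deficit filled, default 100) and the target
minority:majority ratio (default 1:1) are separate knobs from the
neighbour count; the source text uses "k" for both, which the config
deliberately disentangles.

## The CNN-GRU classifier

Architecture: two same-padded 1-D convolutions over time (kernel 3×1;
16 then 32 filters; ReLU), each followed by a max-pool of 2, then a
single-layer GRU over the pooled sequence (50 → 25 → 12 timesteps of
32 features), and a linear head from the final hidden state to the
class scores. The GRU input size is computed from the actual
convolution output rather than hard-coded, since a fixed "32×1×16"
sizing is inconsistent with a 50-sample window under two /2 poolings.
The number of classes defaults to 5 (stages I–V) and is configurable
(a sixth healthy/stage-VI class can be enabled, but no default profile
ships for it).

Training: softmax cross-entropy plus an L2 penalty `½·λ₂·Σ‖W‖²` on the
weight matrices (not biases), minimized with Adam (β = 0.9/0.999) at
the tuned initial learning rate, batch size 16, per-epoch reshuffling
from a seeded generator. Channels are standardized with mean/std
fitted on the training windows only. The network layers and their
backward passes are implemented directly in NumPy (`nn.py`) — dense
float64, hand-derived gradients, verified against central finite
differences in the test suite. At these model sizes (thousands of
parameters) an epoch over a few hundred windows takes ~0.1 s on one
core, so no GPU framework is needed.

The nominal training budget is 600 epochs; the packaged default run
config uses 120 epochs and a 30-epoch budget inside the search, which
is where accuracy saturates on the synthetic profiles — the desk-scale
problem sizes used throughout the docs and tests are the package's own
choice.

## Whale optimization algorithm

WOA minimizes a cost over a box. Each iteration every agent takes one
of three moves: with probability ½ a logarithmic spiral toward the
incumbent best, `X' = X* + |X* − X|·e^{bl}·cos(2πl)` (b = 1,
l ~ U[−1, 1]); otherwise, with `A₁ = 2a·r₁ − a` and `C₁ = 2r₂`, either
encirclement of the best `X' = X* − A₁·|C₁X* − X|` when |A₁| < 1 or
exploration around a uniformly chosen agent
`X' = X_rand − A₁·|C₁X_rand − X|` when |A₁| ≥ 1. The convergence
parameter `a = 2 − 2t/T` decays linearly from 2 to 0. Positions are
hard-clipped to the bounds (the standard convention), the incumbent
best is elitist, and the best-cost trace is non-increasing.

Randomness granularity is a genuine design choice because the update
equations are stated component-wise: r₁, r₂ and the branch probability
p are drawn once per agent per iteration, while the spiral parameter l
is drawn per coordinate. The per-coordinate spiral matters: with a
single scalar l (and scalar A₁·D moves whose components are nearly
equal once the population has collapsed), every exploitation move is a
rank-one shift — all coordinates move by the same constant — which
cannot refine a residual vector with mixed-sign components, and the
search stalls early on shifted optima such as F6. Per-coordinate l
restores component-wise refinement and reproduces the expected
benchmark magnitudes on all four test functions.

Hyperparameter search: 8 agents, 5 iterations, dimension 3 over
(learning rate ∈ [1e-4, 1e-1], hidden units ∈ [10, 30], L2 ∈
[1e-5, 1e-2]); hidden units are rounded on decoding. The fitness of a
candidate is its validation error rate (1 − accuracy) after a reduced
training budget — the objective is otherwise unspecified, and error
rate matches the minimization framing. The expert-experience control
configuration is hidden 10, learning rate 1e-3, L2 5e-5.

### Baselines and benchmark functions

The GA baseline is real-coded: tournament selection (size 3), whole
arithmetic crossover with uniform mixing weight, Gaussian mutation with
per-gene probability max(1/d, 0.05) and a step size annealed linearly
from 10 % to 0.1 % of the box span, and one-elite survival. The PSO
baseline is global-best with inertia 0.7, cognitive/social weights
1.5/1.5, and velocity clamped to half the box span. Both share the
seeding, clipping and elitist-trace contracts.

Benchmark functions (conventional settings: dimension 30, 30 agents,
500 iterations, median of 5 seeds):

| name | definition | bounds |
|------|------------|--------|
| F1 | Σ xᵢ² | [−100, 100] |
| F2 | Σ\|xᵢ\| + Π\|xᵢ\| (Schwefel 2.22) | [−10, 10] |
| F6 | Σ (xᵢ + 0.5)² | [−100, 100] |
| F7 | Σ i·xᵢ⁴ + u, u ~ U[0, 1) per evaluation | [−1.28, 1.28] |

F2 and F6 are implemented in their standard forms (absolute values in
F2, the square in F6), which the printed shorthand elides. F7's noise
is drawn from a per-run seeded stream, once per objective evaluation;
its best observed cost is bounded below by the smallest noise draw, so
it cannot reach zero.

## Evaluation metrics

From the confusion table (rows = true, columns = predicted):
accuracy = trace/total; per-class precision Pᵢ = TPᵢ/(TPᵢ+FPᵢ) and
recall Rᵢ = TPᵢ/(TPᵢ+FNᵢ); macro-P and macro-R are unweighted class
means. The default macro-F1 is the harmonic mean
2·macro-P·macro-R/(macro-P+macro-R); the alternative
mean-of-per-class-F1 convention is also computed and reported
(`macro_f1_mean_of_class`), since published scores do not always say
which was used. Classes with a zero denominator score 0 with a logged
warning — conservative, deterministic, and never silently excluded
from the mean. Micro-averaged metrics coincide with accuracy and are
not separately exposed.

## Numerical and degenerate-input choices

- All randomness descends from explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence.spawn` per cycle); reruns
  with the same config reproduce artifact hashes bit-for-bit.
- Truncated-normal draws (peak angle, scores) use rejection sampling;
  profile means sit far from the bounds so rejection is rare.
- A cycle shorter than the window yields zero windows, not an error; a
  non-positive stride is an error.
- SMOTE with a minority class smaller than k+1 raises an error naming
  the class rather than silently shrinking k.
- An objective returning a non-finite value aborts the optimizer run
  with the offending position in the message.
- `smote_sample` evaluates the convex combination as (1−λ)A + λB so the
  λ = 0 and λ = 1 endpoints are exact in floating point.
- Sigmoid inputs are clipped to ±60 before exponentiation.
- The train/valid/test split is stratified by stage at cycle level and
  guarantees, where group sizes allow, at least one cycle per stage in
  each part.

## Desk-scale study conditions

The tests and examples run on one CPU core in minutes, with sizes
chosen once as the package's defaults:

- classifier accuracy check: 10 cycles per stage, 8 s cycles, stride
  25, 60 epochs — accuracy ≥ 0.95 on the default profiles;
- tuned-vs-control comparison: 8 cycles per stage, stride 50,
  15-epoch fitness budget, 60-epoch final training, median over
  3 seeds;
- stride comparison (25 vs 50): 8 cycles per stage, 80 epochs, median
  over 5 seeds. On the well-separated default profiles both strides
  typically saturate near perfect accuracy, so this check confirms the
  direction (denser windows never hurt) rather than reproducing a gap.

## Known limitations

- The synthetic generator's per-stage distributions are invented
  (documented in one YAML file); absolute accuracies on it say nothing
  about clinical data, and the clinical correlation analysis
  (expert agreement) requires patients and is out of scope.
- The assessment-score channel is sampled, not computed by the upstream
  fuzzy-network scorer it represents.
- SMOTE operates on flattened raw windows; no time-series-aware
  distance (e.g. DTW) or borderline/ADASYN variants.
- The scene mapping stops at control parameters; no rendering, physics
  or hardware control.
- GA/PSO baselines are deliberately plain; their benchmark entries are
  sanity bounds, not a metaheuristics study.
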