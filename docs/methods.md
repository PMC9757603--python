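# Methods

## Model

Observed joint velocities of a redundant chain are modeled, per time-step
`k`, as

    q_dot_k = J#_k(W) x_dot_k + v_k,        J_k v_k = 0

where `J#_k(W) = W^-1 J_k' (J_k W^-1 J_k')^-1` is the weighted
pseudo-inverse and `v_k` a null-space velocity. `W` is diagonal with
entries in `(0, 1]`; since scaling `W` cancels in `J#`, weights are
max-normalized (largest weight exactly 1). The weights are time-invariant
and state-independent over the fitted dataset: the metric is *spatial* —
it averages the coordination strategy over the movement and cannot resolve
temporal ordering of joint recruitment. A purely kinematic formulation is
used throughout; dynamics (inertia, gravity, joint torques) are only
captured indirectly through the velocities they produce.

## Estimation procedure

Weights are identified by alternating two stages until the mean per-sample
residual falls below a threshold:

1. **Evaluation.** With the current estimate `W_bar`, a fraction `gamma`
   of the unexplained velocity is attributed to the null space,
   `v_bar_k = gamma (q_dot_k - J#_bar x_dot_k)`, and the residual
   `e = mean_k ||(1 - gamma)(q_dot_k - J#_bar x_dot_k)||` is recorded.
   Evaluation precedes update, so `error_trace[0]` always reports the fit
   of the conventional identity weight matrix. We compute the projected
   velocity through `x_dot` rather than `J q_dot`; the two coincide under
   forward consistency, and this form makes `gamma = 1` an exact fixed
   point (zero residual, no update) even on measured recordings that are
   only approximately consistent.
2. **Update.** With `u_bar_k = J_k'(J_k W_bar^-1 J_k')^-1 x_dot_k` the
   model reads `W (Q_dot - V_bar) = U_bar`; multiplying by `Q_dot'` and
   exploiting diagonality rearranges it into an `n^2 x n` linear system in
   the weight vector, solved as a box-constrained QP
   (`1e-6 <= w_i <= 1`) and max-normalized. The QP is solved by projected
   quasi-Newton iterations (L-BFGS-B with analytic gradient) warm-started
   from the clipped unconstrained minimizer; the problem is convex, and a
   dense-grid oracle guards the solver in the tests.

The update is quasi-static — `U_bar`, `Psi_bar`, `Omega_bar` are frozen at
the current estimate while `W` is re-solved — so convergence is heuristic,
not guaranteed. Two failure modes are real and documented by the test
suite: with a thin null space (e.g. 4 joints, 3 task dimensions) the
iteration can settle at a slightly biased fixed point (~0.04 in weight
units on noise-free data), and at small `gamma` on data whose null-space
and task velocities are correlated the weights can converge to a
qualitatively wrong ordering. Both are properties of the procedure itself,
visible in the two-joint benchmark.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `gamma` | 0.9 | null-space projection ratio in [0, 1]; a conservative fixed value trading convergence speed for optimality. A schedule `gamma_{t+1} = gamma_t + rate (1 - gamma_t)` (defaults 0.6/0.6) is supported: aggressive early updates, stationarity late. |
| `error_threshold` | 1e-3 | stop when the mean per-sample residual norm (units of joint velocity) drops below this. |
| `max_iterations` | 100 | update budget; exhaustion flags `converged=False` on the result rather than raising. |
| `weight_lower_bound` | 1e-6 | strictly positive lower box bound — `W` must stay invertible; weights at the floor are indistinguishable from zero at reporting precision. |
| `qp_tolerances` | 1e-9/1e-9/1e-12 | optimality / constraint / step tolerances forwarded to the QP solver. |
| `overspecified_joints` | () | joints whose Jacobian column lies outside the span of the others; their weight is unidentifiable, pinned to 1 after each QP and excluded from normalization. Supplied explicitly; an opt-in least-squares detector (`detect_overspecified_joints`) flags candidates. |
| `min_task_speed` | 1e-8 | samples with `||x_dot||` below this floor (rest periods) are dropped from the linear-system assembly; they carry no task information and destabilize `u_bar`. |

Choosing `gamma`: on data whose null-space motion is uncorrelated with the
task (the random benchmark), small `gamma` converges fastest and `gamma`
mostly trades speed for nothing. On realistic, correlated data the choice
matters: too small misattributes null-space motion to the task;
`gamma >= 0.6` recovers the nominal strategy in the two-joint benchmark.
There is no universal optimum; 0.9 is a safe default, the schedule a
faster alternative when early iterations are trusted.

## Numerical choices

- Singularity: the reciprocal condition number of `J W^-1 J^T` below
  1e-10 raises a `SingularJacobianError` naming the offending sample.  No
  damping is applied anywhere — a damped inverse would silently bias the
  weight estimates the package exists to compute.
- Consistency: samples may be validated strictly
  (`||x_dot - J q_dot||` within 1e-6 relative) or leniently (default),
  because measured recordings carry numerical-differentiation noise.
- Normalization ties: division by the maximum maps all tied maxima to 1;
  no tie-breaking is needed.
- The estimator is deterministic given its inputs; seeds only affect the
  synthetic generators.
- Vectors are column-oriented; Jacobians have task dimensions as rows and
  joints as columns.

## Synthetic benchmarks

The generators emit datasets that satisfy the model exactly with a known
`w*`, so estimator error is measurable.

**Random chains.** Per sample: iid standard-normal Jacobian (resampled on
the measure-zero event of rank deficiency), iid standard-normal latent
task velocity, and noise `N(0, sigma)` projected onto the sample's null
space through the nominal projector. Defaults: 5 joints, 3 task
dimensions, 500 samples, `w* = [1, 0.8, 0.6, 0.4, 0.2]`, `sigma = 0.2`.
The emitted `x_dot` is `J q_dot`, so consistency is exact. Because the
raw description of this benchmark (everything iid) cannot identify any
weights, the generative reading — joint velocities synthesized through
`J#(w*)` from a latent task draw — is used; it is the only reading under
which `w*` is recoverable. With `sigma = 0.2`, `gamma = 0.6`, QP
tolerances 1e-3 and 100 repetitions, the mean final weight-error norm is
about 0.06–0.07; it shrinks with `sigma`.

**Two joints, one task dimension.** `J = [1, 1]` (serial prismatic
joints), `w* = [1, 0.01]`, proportional tracking (gain 1.5 s^-1) of a goal
that steps 1 → 1.5 → 0.5 at t = 2 s and 3 s, integrated at dt = 0.1 s for
6 s (60 samples). The null-space policy projects `[-1.0 q_1, 0]` through
the nominal projector, driving the first joint to zero by the end of the
run. The policy gain of 1.0 (and the tracking gain below 2) keeps the
first joint's null-space motion comparable to its tiny task motion; this
regime is the point of the benchmark — `gamma = 0` then converges to the
*wrong* ordering (the task attributed to joint 1), `gamma >= 0.6` recovers
`w_2 / w_1 <= 0.1`, and the 0.6/0.6 schedule converges in a handful of
iterations where fixed `gamma = 0.9` exhausts its budget.

**Assistive virtual elbow.** A 3-link planar chain (hip, shoulder,
prosthetic elbow; links 0.5/0.3/0.35 m). A scripted human driver moves the
end point along minimum-jerk segments between workspace targets (8
segments of 3 s at dt = 0.01 s by default), realized on the two proximal
joints through the square sub-Jacobian with proportional end-point
correction and a +/-4 rad/s rate limit. The elbow runs the assistive law
`q3_dot = J3# v - N3 K (q - q_hat)` with `W = diag([1, 1, 0.15])`,
posture gains `K = diag([2, 0.2, 0])`, rest posture `[0, -2.7, 0]` rad and
a first-order velocity filter `v_dot = -40 (v - x_dot)`; the elbow angle
is clamped to `[0, pi]`. Estimated weights on this data order hip >=
shoulder >= elbow — assistance makes the distal joint cheapest — and the
contribution coefficients concentrate on the elbow.

What the generators do **not** emulate: measurement noise on `x_dot` and
`J` (their samples are exactly consistent), soft-tissue artifacts, joint
limits other than the virtual elbow's, fatigue or any time variation of
the strategy, and torque-level dynamics. Passing tests on these benchmarks
therefore demonstrate correctness of the estimator under its own model
assumptions, not robustness to every artifact of motion-capture data.

## Cohort analyses

Per-participant weights are estimated from all trials of a condition
concatenated column-wise (the default grouping; per-trial estimation is
available and agrees on noise-free synthetic cohorts). For studies with a
4-joint chain and 3-D task where the distal joint is over-specified, its
index is declared so the weight is pinned to 1 and excluded from
normalization.

Null-space utilization re-decomposes every recorded trial twice — under
the estimated weights and under identity weights — and aggregates mean and
SD per time step. On generative data the estimated weights leave an order
of magnitude less null-space motion than the identity assumption, which is
the package's argument for estimating rather than assuming `W`.

Condition contrasts use paired Hotelling's T² on per-participant weight
components: `T² = N d_bar' S^-1 d_bar` on the difference vectors, exact
F transform `(N - p) / (p (N - 1)) T²` with df `(p, N - p)`. Components
pinned by convention must be excluded (their differences are degenerate);
with 17 participants and 2 free components the df are (2, 15). All
differences exactly zero returns `T² = 0, p = 1`; a singular difference
covariance raises with advice to drop degenerate components. p-values
below 1e-3 display as "< 0.001".

Group-level contribution coefficients support three documented
aggregations — median weights then transform (default), mean weights then
transform, and transform-then-median (renormalized) — because the choice
is not dictated by the model; all three are exposed and tested.

## Known limitations

- Convergence of the alternating scheme is heuristic; `converged=False`
  with the trace attached is a first-class outcome, not an error.
- Weight identifiability requires informative data: rich Jacobian
  variation, enough samples (a warning fires below `n^2`), and a null
  space that is actually exercised. One-dimensional null spaces can leave
  a small systematic bias (see above).
- The residual threshold is an absolute velocity scale; datasets in
  different units need a rescaled threshold.
- MAT-file reading targets the documented participant/condition/target/
  trial layout; other layouts should be converted to the interchange
  format.
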