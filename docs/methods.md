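# Methods

`driftlab` studies how continued training under noise moves an
overparameterized network along its manifold of equally good solutions,
and how the same signatures (fewer active cells, sharper spatial tuning)
can be measured in multi-session place-cell recordings. This note
documents the models, conventions and numerical choices; nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Corridor task

An agent shuttles along a corridor `[0, Lx] × [0, Ly]` at speed `V0`. Its
heading is a deflection θ around the corridor axis performing a Gaussian
random walk (variance `sigma_theta_sq` per step), clamped to ±π/2; the
per-step displacement is `V0·(sin θ, ±cos θ)`, with the y-sign flipping
whenever the agent comes within `Ly·L_buffer` of either end and the x
coordinate reflecting off the side walls (mirroring θ). The exact
functional link between heading and lateral displacement is a modelling
choice; we use the bounded sine form so the speed stays `V0` and the
forward component is `V0·cos θ ≈ V0` for small deflections.

The walls carry a fixed texture: a standard Gaussian vector of length
`L_walls = 2(Lx+Ly)·L_vis`, smoothed circularly with a Gaussian kernel of
variance `K_smooth · L_walls`. The perimeter is parameterized
counter-clockwise from the origin (bottom, right, top, left walls), and
fractional texture coordinates are linearly interpolated with
wrap-around. Each frame casts `L_vis` rays spanning `theta_vis` around
the heading and reads the texture at the ray–wall intersections. For the
training task the texture is normalized to unit variance so the
prediction loss is O(1).

The dataset pairs `X_t = [frame_t, v_y/V0]` with `Y_t = frame_{t+1}`:
the velocity channel resolves the direction ambiguity of pure frames.
The reference geometry (`Lx=1, Ly=10, V0=0.4, L_vis=15`, 64 samples)
gives the agent ~3 laps of coverage, enough for direction-split tuning
curves at 20 bins per direction.

## Network, loss, gradients

A single hidden layer with ReLU: `ŷ = max(0, x mᵀ + b) nᵀ`, trained on
the mean squared error over samples *and* output coordinates. Reported
"baseline-adjusted" loss subtracts the MSE of the constant column-mean
predictor, so a network no better than predicting the mean maps to zero.
Parameters flatten as (m row-major, b, n row-major); unit `h` owns
`m[h,:]`, `b[h]`, `n[:,h]`, so Hessian rows map onto units.

A unit is **active** on an input when its activation exceeds `1e-12`
(a strict positivity test is meaningless in floating point), and active
in a run when it is active on at least one input. The gradient of every
parameter belonging to a unit inactive on all samples is exactly zero —
the mechanism by which sparsification is absorbing in the noiseless
dynamics.

## Gauss–Newton Hessian

Flatness is measured by the Gauss–Newton matrix: the sum over samples
and output coordinates of outer products of model-output gradients,
scaled by `2/(N·K)` to match the MSE Hessian (for vector outputs the
per-sample outer product is summed per scalar output, which keeps the
form well-typed; the scale factor moves all eigenvalues uniformly). At
any interpolating point this equals the exact loss Hessian. The
activity indicator inside the Jacobian uses the same `1e-12` tolerance
as the sparsity metrics, so a dead unit corresponds *exactly* to
`d + 1 + k` zero rows/columns, hence at least that many zero
eigenvalues. Eigenvalues below `1e-8 × λ_max` are counted as zero (the
matrix is PSD by construction; round-off produces ~1e-12 relative
noise). Dense eigendecomposition is capped at 6000 parameters; spectra
are computed at logged checkpoints only.

Two regularizer functionals are tracked: the sum of logs of non-zero
eigenvalues (the quantity update noise implicitly minimizes — its slope
diverges as an eigenvalue approaches zero, which is why small
eigenvalues are driven to exact zeros, i.e. dead units) and the plain
eigenvalue sum (the label-noise regularizer, computed exactly and
cheaply as the closed-form trace when no spectrum is needed).

## Training rules and noise

- **GD + update noise.** The per-step update is
  `θ' = θ − η(∇f + ζ)`, `ζ ~ N(0, σ²I)`: the configured noise variance
  is the variance of a noisy-gradient term, so the parameter-level
  noise has std `η·σ`. Injecting parameter noise of variance σ²
  directly, independent of η, makes the stationary excess loss scale as
  σ²/η per stiff Hessian direction — with the variances studied here
  (0.01–0.1) that destroys the network instead of letting it sit on its
  loss plateau and drift, so the noisy-gradient convention is the one
  under which the phenomenon of interest exists. The `gd_update`
  primitive itself adds noise of a stated variance directly to θ.
- **Label noise.** Fresh Gaussian noise is added to the residual inside
  the loss each step; the resulting gradient is unbiased for the clean
  gradient, and at zero residual the noisy loss averages to the noise
  variance.
- **SED (stochastic error descent).** `θ' = θ − η(f(θ+ξ) − f(θ))ξ`;
  to first order the expected update is `−η σ² ∇f`, so SED is noisy
  gradient descent without gradient access. Its perturbation variance is
  taken from the config's noise-variance field; no extra noise is added.
- **Adam / RMSprop.** Standard formulations (β₁=0.9, β₂=0.999, ε=1e-8;
  RMSprop decay 0.999 shared), no added noise.

One seeded stream drives all noise in a run; the task, the
initialization and the noise stream get independent child seeds of the
run seed. Full-batch gradients are the default (mini-batching is
available for GD). Initialization is N(0, 1/fan-in) weights with zero
biases; the "rich" regime multiplies the weight scale by 0.1. Metrics
(raw and adjusted loss, active fraction, fraction of active units, mean
SI when the task has a latent position) are logged on a geometric
schedule (×1.2), with a parameter checkpoint per log point. Training
aborts if the loss exceeds 10⁶ × its initial value.

The full-batch GD path runs in a JIT-compiled kernel with noise
pregenerated in chunks; its logging semantics match the reference
implementation (record before the update at each log step, once after
the final update). A batched ensemble runner (`train_ensemble`) runs
many GD configurations in lockstep for sweeps; members are
statistically, not bitwise, equivalent to serial runs.

## Metrics

- **Rate maps**: per unit and running direction, mean activity per
  position bin divided by occupancy; unvisited bins are NaN and excluded.
  Occupancy normalizes to a probability over visited bins.
- **Spatial information**: `SI = Σ p_i (r_i/r̄) log2(r_i/r̄)` with
  `r̄ = Σ p_i r_i`; zero-rate bins contribute 0, and a silent unit has
  SI 0. SI is non-negative and invariant to uniform rate rescaling. No
  sampling-bias correction is applied (plug-in estimator); mean SI over
  a population averages active units only, since dead units have no
  tuning. Whether to include dead units as zeros is a genuine ambiguity;
  excluding them is the convention here and is applied consistently.
- **Sparsity**: binarize the unit×input activation matrix at the
  activity tolerance; *active fraction* = mean of the binary matrix,
  *fraction of active units* = fraction of rows with any 1. The first
  never exceeds the second.
- **Rate-map correlation**: per-unit Pearson correlation across bins
  (directions pooled), averaged over units active at both times; units
  with zero-variance maps are excluded and counted.

## Timescales and phases

The sparsification timescale is fit by shifting the
fraction-of-active-units curve so its final value is zero, clipping at
the first point where 90% of the total change is complete (to avoid
fitting plateau noise), and least-squares fitting `a·exp(−t/τ)`
(trust-region, initialized from a log-linear fit). Non-decreasing curves
return a flagged no-timescale result rather than an error. The fit is
time-scale equivariant.

Traces are segmented into the three phases of noisy learning — task
learning, directed drift, null drift — by settling times: phase 1 ends
when the baseline-adjusted loss first *stays* within a tolerance of its
final value, phase 2 when the fraction of active units does. The
package-wide convention ties the loss tolerance to the trace's own
scale: 25% of the total loss drop (noisy plateaus fluctuate, so a
tolerance much below the fluctuation scale would push the "plateau"
into the sparsification phase), and an absolute 0.05 band on the
fraction of active units. A sweep run counts as *converged* when at
least three fitted time constants have elapsed (residual amplitude
e⁻³ ≈ 5%); final-sparsity comparisons across noise amplitudes are made
among converged runs only, since an unconverged run's "final" value
reflects its clipped horizon, not its equilibrium.

## Toy landscape

`L(x, y) = (xy)²` has zero loss on both axes; at `(x₀, 0)` the exact
Hessian is `diag(2y², 2x²)|_{y=0}`, eigenvalues `{0, 2x₀²}` (derivations
that drop the factor 2 from the square's chain rule understate the stiff
eigenvalue; the implementation and its finite-difference oracle agree on
`2x₀²`). Under update noise the walker returns quickly to the manifold
and drifts toward small |x|, where the transverse curvature vanishes.

A known limitation, verified numerically and analytically: the inward
drift near the manifold is `E[Δx] ≈ −σ²/(2x)` per step while x itself
receives additive noise of std σ, so the drift-to-diffusion ratio is
O(1) at every horizon and `E[x²]` is nearly conserved. The *ensemble*
bias is robust (mean and median late-time |x| fall well below the
start), but any per-seed criterion of the form "late |x| below the
start" saturates near ~80% of seeds: once a walker reaches the origin
it explores both flat arms and |x| recurs. Demonstrations and tests of
this module therefore assert the ensemble-level bias.

## Session pipeline

Sessions are 1-D track recordings (time, position, speed, per-cell
activity). Processing mirrors standard chronic-imaging analyses: frames
faster than 1 cm/s are kept; rate maps use 4 cm bins with directions
split; place cells are classified by a circular-shift shuffle test
(activity rolled against position by uniform offsets of ≥ 10 s, cell
accepted when its SI exceeds the 95th percentile of its own null;
count, percentile and minimum shift are configurable since they are
rarely reported consistently). For data styles without spikes, an
active-cell count with a 0.1 Hz minimum-rate filter replaces
classification. Per-session statistics (fraction of place cells or
active-cell count, mean SI over included cells) are pooled by
*experience day* (sessions from interleaved environments with the same
experience index pool their cells) and normalized to each animal's
first session. Trends are ordinary least squares against time with an
intercept and a two-sided t-test on the slope; exactly-constant or
exactly-fit series get p = 1 and p = 0 respectively rather than a
degenerate 0/0 t-statistic.

## Synthetic cohorts

The generator emulates the structure of chronic linear-track
experiments: per animal, Gaussian place fields with random centres and
peak rates (2–8 Hz); per day `d`, each cell is active with probability
`1 − decline_rate·d` (day 0 is all-active, making the first-session
normalization exact and the expected normalized count `1 −
decline_rate·d`, slope `−decline_rate`); field widths shrink as
`(1 − shrink_rate)^d`, producing the rising-SI signature; centres
random-walk by `drift_cm_per_day`. Trajectories are aperiodic
back-and-forth runs with Gaussian speeds (mean 12 cm/s, 5% near-zero
pause frames) sampled at 10 Hz; activity is Poisson counts from
rate × dt. Defaults (8 animals × 10 days × 100 cells × 200 s) mirror a
typical cohort.

What the generator does *not* emulate: calcium indicator dynamics and
event-detection artefacts, theta-phase and speed modulation of rates,
direction-selective fields, remapping, and correlated (non-Poisson)
noise. Passing recovery tests therefore shows the pipeline is unbiased
for this idealized generative family, not that real-data estimates are
unbiased; on real recordings the shuffle parameters and rate filters
materially affect absolute values, which is why trends are computed on
session-normalized statistics.

## Problem sizes

Reference simulation: corridor task, 16 inputs (15 pixels + velocity),
100 hidden units, 64 samples, 2×10⁵ GD steps, update-noise variance
0.05, η = 0.05 — large enough for a clear plateau→sparsification
separation (fitted τ ≈ 8×10⁴ steps vs plateau ≈ 10²–10³). Heavier
multi-run analyses (label-noise comparisons at η = 0.1, the 12-point
noise sweep at 6×10⁵ steps) use a reduced network (9 inputs, 50 hidden,
32 samples), where the same phenomena occur at a quarter of the cost.
Cohort-recovery replicates use 4 animals × 8 days × 60 cells × 120 s.
These sizes are the package's reference configurations; all are plain
config fields.
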