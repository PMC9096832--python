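# Methods

`discountclass` characterizes delay-discounting response patterns three
ways — rule-based screening, a model-free area summary, and data-driven
latent-class modeling — and ties them together so a cohort's latent
classes can be cross-tabulated against the rule-based flags. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic cohorts do and do not emulate.

## The adjusting-amount task and its simulation

In an adjusting-amount (staircase) task the participant repeatedly
chooses between an immediate smaller-sooner reward (SSR, adjustable
amount `s`) and a fixed larger-later reward (LLR, amount `A`) at delay
`d`. The SSR opens at `A/2`; after each choice it moves toward the
participant's indifference value — up by the current adjustment if the
LLR was chosen, down if the SSR was chosen — and the adjustment halves
each trial (`A/4, A/8, A/16, A/32, A/64`). After five choices the final
SSR value is recorded as the indifference point for that delay.

With an adjustment applied after every one of the five choices the
reachable outcomes are exactly the 32 grid points `{A·j/64 : j odd}`,
and the staircase is a bisection: for a deterministic responder with a
fixed subjective value `V(d)`, the recorded point is within `A/32` of
`V(d)`. Whether the fifth choice triggers an adjustment is a task-
implementation detail that published task descriptions leave open; the
package defaults to applying it (`final_adjustment=True`, grid
`A·odd/64`) and exposes the four-adjustment variant (grid `A·odd/32`).
Deterministic agents resolve the measure-zero tie `s = V(d)` toward the
LLR so that enumeration is deterministic. Stochastic agents choose the
SSR with probability `1/(1+exp(−β(s−V(d))))` and consume one uniform
draw per choice from a stream keyed by (agent seed, delay index), so
simulations are reproducible and independent of cohort size.

## Screening rules and AUC

Two rule-based criteria flag non-systematic series, with bounds
expressed as fractions of the undiscounted amount `A`:

* **JB1 (local):** a violation occurs when an indifference point exceeds
  its predecessor by *more than* `c1·A` (default `c1 = 0.20`). The
  comparison is strict — a rise of exactly `c1·A` is allowed — and is
  coded literally as `v_j > v_{j−1} + c1·A` so that exact boundary
  values behave identically however the bound is constructed in floating
  point. A configurable number of violations (default 0) may be allowed.
* **JB2 (global):** the series passes when the last point is below the
  first by *at least* `c2·A` (default `c2 = 0.10`), i.e.
  `v_1 − v_m ≥ c2·A`, a weak inequality.

Point-based AUC normalizes delays affinely onto [0, 1] over the observed
span (no imputed origin at `(0, A)`; measured points only, though
`include_origin=True` prepends one) and values by `A`, then applies the
trapezoid rule. The result is scale-free: invariant to jointly rescaling
`A` and the values, and to affine rescaling of the delays. Lower AUC
means steeper discounting. Missing values are never silently imputed:
the caller chooses `error`, `drop`, or `interpolate` (linear over delay,
interior gaps only) per cohort screen.

## The latent-class linear mixed model

Outcomes are normalized to `y = v/A` and delays to `t = d/120` (so `t`
spans (0, 1] over the standard 1–120-month grid) for conditioning and
cross-magnitude comparability. Each latent class `g` of `G` has its own
line; subject `i` in class `g` satisfies

    y_ij = β0_g + β1_g·t_j + b_i + e_ij,
    b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ²),

with mixing proportions π_1..π_G. The random intercept and residual
variances are shared across classes, which prevents a spurious class
from spiking the likelihood by collapsing its own variance;
class-specific variances are out of scope. Marginally the subject vector
is MVN with compound-symmetric covariance `Σ = σ_b²J + σ²I`, evaluated
through its closed-form inverse and determinant (no dense solves). The
linear trajectory is deliberately the most basic shape able to index
direction and rate of change; curvature misfit is absorbed by the class
structure rather than the link function.

**Estimation.** EM treating both the class label and the random
intercept as missing data. The E-step computes responsibilities
`τ_ig ∝ π_g φ_g(y_i)` (log-space, logsumexp) and the conditional normal
moments of `b_i | y_i, g` (closed form via the marginal covariance — no
quadrature). M-steps are exact: `π_g = mean_i τ_ig`; `β_g` by τ-weighted
least squares on intercept-adjusted outcomes; variances from τ-weighted
second moments, using the freshly updated `β_g` for the residual variance
(a conditional-maximization step). Every step increases the
observed-data log-likelihood, which the test suite asserts per
iteration. With `G = 1` and no random intercept the first M-step is
already the OLS maximum-likelihood solution; with a random intercept the
fit matches ML (not REML) linear mixed-model estimation.

**Starts and convergence.** One start comes from k-means (scikit-learn)
on per-subject OLS (intercept, slope) pairs — k-means is used only as an
initializer, never as the classifier — and the remaining `n_starts − 1`
(default 5 total) are random perturbations of it; the best final
log-likelihood wins, with a converged fit preferred over an equal-scoring
non-converged one. Iteration stops when the relative log-likelihood
change falls below `tol_loglik = 1e-8` and the largest parameter change
below `tol_params = 1e-6`, or at `max_iter = 500`. These defaults
resolve the likelihood far beyond the information-criterion differences
that drive class selection at cohort sizes around 10³ while keeping a
full 1–8-class sweep on 1 198 subjects under half a minute on one core.
Numerical guards: residual variance floored at 1e-8, class weights
floored at 1e-10 inside logarithms, and a class whose total
responsibility falls below 1e-6·N marks the fit non-converged with a
diagnostic.

**Label switching.** The mixture likelihood is invariant to permuting
class labels, so reported classes are canonicalized by fitted slope
ascending (ties by intercept). Class numbering is therefore a package
convention; it is not comparable across studies that order classes
differently.

**Model comparison.** For each `G` the criteria table reports
`AIC = −2ℓ + 2p`, `BIC = −2ℓ + p·ln N`, and the sample-size-adjusted
`SABIC = −2ℓ + p·ln((N+2)/24)`, with `p = (G−1) + 2G + 1 +
[random intercept]` and `N` the number of *subjects* — the independent
sampling units in the mixture, not the number of observations.
Selection uses the lowest SABIC (AIC is reported alongside). Whether the
reference analyses of this task family included a random intercept is
not documented, so both variants are supported via the
`random_intercept` flag; neither is claimed as "the" canonical model.

## Synthetic cohorts

The generator plants known class structure so that recovery, selection
and screening behaviour can be tested against ground truth. Class kinds:
`hyperbolic` (mean `A/(1+k_i d)`, subject rates `k_i` log-normal),
`riser` (mean `A(c0 + c1 x)` rising in the normalized delay `x`), and
`flat` (mean `A·c0`). Per-subject intercepts and per-observation
Gaussian noise are added on the indifference-point scale — fast and
sufficient for model tests — and values are clamped to `[0, A]`
(mirroring the task's floor and ceiling; no resampling) and by default
snapped to the titration grid `A·odd/64`. A `behavioral` mode instead
drives a deterministic titration agent with each subject's latent value
profile through the five-choice staircase, integrating the modules end
to end; there, grid quantization is inherent rather than imposed.

The default large-study recipe (`hcp_like_recipe`) has 1 198 subjects on
the six standard delays: five hyperbolic classes with weights
(0.44, 0.25, 0.14, 0.08, 0.05) and `ln k` means (0, −2.3, −3.7, −5, −7),
sd 0.5 — spanning mean AUC from roughly 0.05 (near-immediate
devaluation) to 0.9 (shallow discounting) — plus a rising class at
weight 0.006 (`c0 = 0.25`, `c1 = 0.5`) emulating the small
opposite-direction subgroup such studies report, and a flat class at
weight 0.034. Residual SD is 0.05·A, with one mid-rate hyperbolic class
at 0.20·A standing in for the erratic minority that drives local
(JB1) violations in real cohorts; between-subject intercept SD is
0.02·A. Under these defaults the generated cohort's pass rates land
near 89% (JB1), 92% (JB2) and 82% (both) — within the range large
adjusting-amount studies report (roughly 70–90% per criterion).

What the generator does **not** emulate: magnitude effects linking the
$200 and $40 000 tasks within a subject, demographic covariates,
reaction times, autocorrelated or heavy-tailed noise, and order effects
across delays. Passing tests on these cohorts therefore demonstrate that
the estimation and screening machinery is correct under the stated
generative model, not that any particular real cohort has a given class
structure.

## Recovery and selection benchmarks

Parameter- and class-recovery checks use a planted two-class mixture
(N = 300): a flat class at `0.75·A` and a rising class from `0.2·A` to
`0.6·A`, residual SD `0.02·A`, subject SD `0.03·A`, grid snapping off.
Both shapes are exactly linear in normalized delay, so the fitted model
is correctly specified and "fixed effects recovered within Monte-Carlo
error" is well defined; snapping is disabled because grid quantization
adds non-Gaussian noise that would bias that comparison. Trajectories
differ by at least 7 residual SDs at every delay. Across 20 replicates,
classification accuracy is essentially 100%, fixed effects sit within
3 Monte-Carlo standard errors of truth, and the lowest-SABIC rule picks
the planted class count in ≈90% of replicates (SABIC's known mild
tendency to overextract accounts for the occasional `G+1` pick; the
extra-class likelihood gains involved are genuine features of mixture
asymptotics, not optimization failures).

The end-to-end benchmark runs the full pipeline on the default
1 198-subject recipe: the sweep selects several classes, and the class
capturing the planted risers is flagged "characteristically distinct"
under the package's convention (within-class both-criteria pass rate
below 50% — the flag threshold is a package convention for surfacing
qualitatively deviant subgroups, stated in the output). Noise-free
risers fail the global criterion by construction, so their both-pass
rate is exactly 0%.

## Reporting conventions

Cross-tabulations report per-class n and percentages at full precision
in CSV (integer rounding is for display only). AUC distributions per
class use mean, SD, median and type-7 (linear-interpolation) quartiles —
the quartile convention is stated because summary tables in the
literature rarely specify one. Percentages from the class cross-tab
reconcile with cohort-level screening rates by class-size weighting.
Every pipeline run writes a JSON manifest (inputs, seeds, parameter
counts, convergence diagnostics) alongside the report tables, and the
whole bundle is byte-reproducible given (input, config, seed).

## Known limitations

* Linear trajectories only; hyperbolic/hyperboloid link functions,
  spline shapes, class-membership covariates and class-specific
  random-effect structures are out of scope.
* Shared variances across classes mean a genuinely heteroscedastic
  class (like the planted erratic one) is identified through its mean
  trajectory and misfit, not through its variance.
* SABIC-based class counts are sample-size dependent; larger cohorts
  support more classes, and the selected count should be read as a
  description of the sample, not an estimate of a true number of
  behavioral types.
* The EM fit guarantees monotone likelihood ascent, not a global
  optimum; multiple starts mitigate but cannot eliminate local maxima.
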