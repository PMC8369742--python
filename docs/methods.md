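# Methods

## The model

`gaprog` models longitudinal geographic-atrophy (GA) lesion sizes
y_ijt (mm², eye i of patient j at follow-up time t years) as linear
trajectories in *disease age* on a Box-Cox transformed scale,

    z = f_λ(y) = (y^λ − 1)/λ   (λ ≠ 0),   log y  (λ = 0).

The central idea is that every eye follows essentially the same
enlargement process and differs mainly in how long the disease has
already been present at study entry. Writing Δ_i ≥ 0 for that unknown
disease duration and assuming Δ_i ≈ N(μ_Δ, σ_Δ²) across eyes:

* **No covariables.** z_ijt = μ_θ + β t + ζ_j + α_i + ε_ijt with
  patient effects ζ_j ~ N(0, σ_ζ²), eye-within-patient effects
  α_i ~ N(0, σ_θ²) and residuals ε ~ N(0, σ²). Here μ_θ = β μ_Δ and
  α_i = β(Δ_i − μ_Δ): an ordinary nested mixed model.

* **With covariables.** Risk factors x_i (binary 0/1 indicators,
  patient-level, replicated to both eyes; time-constant) act on the
  enlargement *rate* before and after entry:

      z_ijt = (β + β_x'x_i) · (μ_Δ + γ_i + ζ_j + t) + ε_ijt.

  Expanding this product ties the slope of t, the slopes of x_i·t and
  the loadings of both random effects to the same per-eye rate
  x̃_i = β + β_x'x_i (the *working covariable*), so the model is a
  mixed model with hard cross-parameter constraints.

All random effects are mutually independent and independent of ε.
Covariable coding follows the absent-level-is-1 convention
(`hypertension_no`, `hypercholesterolemia_no`), so a positive slope for
an `_no` indicator means faster enlargement when the risk factor is
absent.

## Fitting

**Inner mixed-model fits** maximize the exact Gaussian marginal
likelihood per patient block. For fixed variance ratios
ρ_ζ = σ_ζ²/σ², ρ_Δ = σ_Δ²/σ², the block correlation matrix is
I + ρ_ζ uu' + ρ_Δ Σ_e u_e u_e' with known loadings u (the working
covariable, or 1); fixed effects are profiled by GLS and σ² in closed
form, leaving a 2-parameter optimization (Nelder–Mead on log ratios,
xatol 1e-6). The low-rank structure is handled by the Woodbury
identity with q×q cores (q = 1 + eyes per patient), batched across
patients, so one likelihood evaluation is a few small matrix
operations. Variances are optimized on the log scale; an estimated SD
below 1e-6 is reported as 0 with a boundary flag. ML (not REML) is
used throughout: AIC comparisons across λ require it.

**The constrained model** is fitted by the iterative
working-covariable algorithm: (i) compute x̃_i = β̂ + β̂_x'x_i from
the current estimates; (ii) refit the linear mixed model
z = β t + β_x'x_i t + μ_Δ x̃_i + x̃_i γ_i + x̃_i ζ_j + ε in which x̃_i
is a fixed regressor and the known loading of both random effects;
repeat until the maximum relative change of (β, β_x, μ_Δ) is below
`tol` (default 1e-6, `max_iter` 50). The default start is x̃_i = 1; a
warm start can be supplied, and the fixed point does not depend on it.
On FAM-like cohorts the algorithm converges in about 5–7 outer
iterations.

**The fixed point is not the exact constrained MLE.** The inner fit is
stationary only holding x̃ fixed; the constrained likelihood's
gradient through x̃ (the covariance loadings, and the μ_Δ·x_s mean
direction that lies outside the inner model's column span) is nonzero
at the fixed point. `brute_force_ml` exposes the exact alternative: a
direct optimization of the closed-form constrained likelihood with x̃
recomputed inside the objective, intended as an independent
cross-check on small cohorts. On 20–40-eye cohorts the exact optimum
is higher by 0.1–1 log-likelihood units and single coefficients can
differ by several percent; on the no-covariable model (no constraint)
the two agree to ~1e-12. The iterative estimator is the production
path because it is what the field's software stack supports and what
the published coefficient values refer to.

**Stability intercept.** An optional free intercept can be added to
the working-covariable model (`include_stability_intercept`). It is
*off by default*: the x̃ column spans only a narrow range when
covariable effects are modest (≈0.33–0.53 at the default effect
sizes), so a free intercept is nearly collinear with it and puts
(c₀, μ_Δ) on a flat likelihood ridge — measured across replicates the
SD of μ̂_Δ grows from 0.45 to 2.15 years. The closed-form GLS inner
fits need no numerical-stability aid, and the narrow published
confidence interval for μ_Δ is only reproducible without a floating
intercept. The flag remains for experiments.

## Transformation selection

For each λ on a grid (default 0, 0.05, …, 1.50) the model is fitted to
f_λ(y) and compared by AIC *on the original scale*: the density
transformation theorem adds the log-Jacobian (λ−1)·Σ log y to the
transformed-scale log-likelihood. n_params counts the estimated fixed
effects, the two free variance components and σ²; λ itself is not
counted (it is fixed within each fit; a constant offset cannot move
the argmin). Ties break toward the smaller λ. Warm starts carry the
variance ratios and working covariables to the next grid point.

## Age-of-onset estimation

GA is clinically diagnosable from a lesion area of 0.05 mm² (250 µm
minimum diameter), the default threshold. Solving the fitted model for
the time at which the expected transformed size equals f_λ(threshold):

    no covariables:  t̂₀ = [f_λ(thr) − (μ̂_θ + ζ̂_j + α̂_i)] / β̂
    covariables:     t̂₀ = [f_λ(thr) − x̃_i(μ̂_Δ + ζ̂_j + γ̂_i)] / x̃_i

with empirical-Bayes conditional modes ζ̂, γ̂ (closed-form GLS solve
per patient at the plugged-in ML parameters). t̂₀ is negative for
onset before study entry, and the onset age is
age_at_baseline **plus** the signed t̂₀ — the only sign convention
under which estimated onset ages fall below entry ages. The estimated
disease duration Δ̂ = μ̂_Δ + ζ̂ + γ̂ is reported alongside; at a
threshold with f_λ(thr) = 0 (i.e. 1 mm²), t̂₀ = −Δ̂ exactly. Eyes with
x̃_i = 0 (or β̂ = 0) get a missing onset with a reason. Both mean and
median cohort summaries are exported.

## Prediction on the original scale

Because f_λ⁻¹ is convex for λ < 1, naively back-transforming the
linear predictor underestimates the expected size (Jensen's
inequality). The smearing estimator averages the back-transform over
r = 10,000 residuals resampled (seeded, with replacement) from the
fitted model's empirical residual pool — the same residual vector the
diagnostics table reports. Draws whose inverse does not exist
(λz + 1 ≤ 0) are dropped and counted; a warning is raised if a target
drops more than 1% of draws. The smearing ≥ naive ordering is exact in
the enumeration (r → ∞) limit for a zero-mean pool; at finite r it
holds up to Monte-Carlo error.

In-sample accuracy is summarized as the RMSD between observed and
smearing-predicted sizes, optionally profiled across λ. The
next-observation experiment removes the last visit of every eye with
more than three visits, refits **once** on the reduced data (a single
shared training fit, chosen over per-eye refits for determinism and
cost), and predicts each held-out visit with the training fit's
conditional modes.

## Bootstrap inference

Residuals remain visibly non-Gaussian even after transformation, so
confidence intervals come from a cluster bootstrap: whole patients are
resampled with replacement (keeping all their eyes and visits;
duplicated patients get fresh identifiers), the model is refitted at
the fixed, pre-selected λ, and percentile intervals are taken over
replicate estimates (default B = 1000, level 95%). λ is not
re-selected per replicate — that would change the estimand. More than
10% replicate fit failures abort with an error.

## Synthetic cohorts

The generator draws from the covariable model on the transformed scale
and back-transforms. Defaults emulate the published study cohort:
101 patients, 48.5% bilateral; visit counts 2/3/4 with probabilities
0.2475/0.2278/0.2278 and 5–9 uniform within a pooled 0.297; lognormal
visit spacing with median 0.9 y and log-SD 0.5 (mean follow-up ≈ 3.3 y
— per-visit spacings are not published, so this is a design choice);
baseline age N(75.61, 7²) (the SD is a choice; only median/IQR/range
are published); risk-factor-absent prevalences 0.71
(hypercholesterolemia) and 0.44 (hypertension); generative parameters
λ = 0.45, β = 0.42, β_hyperchol-no = 0.11, β_hypertension-no = −0.09,
μ_Δ = 4.74, σ_Δ = 1.83, σ_ζ = 4.03, σ = 0.42. A truth table (per-eye
Δ_i, γ_i, ζ_j, x̃_i; per-row ε and z) accompanies every cohort.

**Positivity truncation.** The Gaussian model assigns mass to
transformed sizes with no Box-Cox preimage (λz + 1 ≤ 0), so rows whose
back-transform is undefined or below a floor of 0.01 mm² (the minimum
representable lesion size) are repaired by redrawing ε (up to 100
times), and irreparable eyes are redrawn entirely; both counts are
reported (≈1–2% of eyes at the defaults; >50% rejection is an error).
This left-truncation is intrinsic — no faithful positive-data
generator can avoid it — and has two visible consequences at the
default settings: μ̂_Δ recovers with a small upward shift (≈ +0.1 to
+0.15 years at 101 patients), and the AIC-selected λ is pulled down by
up to one grid step at λ = 0.45 (about two at λ = 1.0, where ~5% of
eyes touch the y > 0 boundary regardless of the floor). Fitting the
no-covariable model to covariable-generated data shifts λ̂ down
further (unmodeled rate heterogeneity favors a stronger
transformation). Passing recovery tests therefore demonstrate
estimator correctness under the stated design, not robustness to the
many features of real cohorts the generator omits: informative visit
schedules and dropout, grading error distinct from ε, non-Gaussian
random effects, and time-varying covariables.

## Problem sizes and numerical choices

Simulation-backed checks use 101-patient cohorts (10 replicates for
transformation selection, 20 for coefficient recovery), 14-patient
cohorts for the brute-force cross-checks, and 50-patient cohorts with
B = 200 and 50 outer runs for bootstrap-coverage evaluation — sizes
chosen to keep the full evaluation on a desk machine while leaving
each check's Monte-Carlo error well below its decision band. Residual
variance is floored at 1e-12 (exactly noise-free inputs); conditional
modes solve dense per-patient systems; degenerate design columns
(all-zero covariables) fall back to a minimum-norm least-squares
solution.
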