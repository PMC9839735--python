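# Methods

`soundwell` models the association between workplace sound level and a latent
physiological-wellbeing variable observed through two heart-rate-variability
outcomes, and provides a synthetic-cohort generator whose data-generating
process is exactly the model the analysis assumes. This note documents the
models, the generator, the numerical choices, and the limits of what the
tests establish.

## The latent wellbeing model

For participant *j*, 5-minute epoch *i*, and outcome *h* ∈ {SDNN,
normalized-HF} (both standardized on the training split):

    y_hij = λ_h · η_ij + ε_ij^(h),      ε_ij^(h) ~ N(0, σ_h²)
    η_ij  = β₀ + γ₀j + Σ_k β_k x_kij + Σ_m γ_mj z_mij
    γ₀j ~ N(0, σ_γ₀²),   γ_mj ~ N(0, σ_γm²)

A single latent score η drives both outcomes through factor loadings λ_h.
Because the latent scale is arbitrary, **λ₁ (SDNN) is fixed at 1**: SDNN
anchors the scale and the sign (higher HRV = higher wellbeing); λ₂ is free,
and its sign is identified through the data rather than a constraint. The
within-epoch latent disturbance is not separately identified from the
outcome errors and is folded into σ_h.

Fixed effects x: two hinge sound terms (below/above the 50-dBA knot, built
on raw dBA as `min(s, 50)` and `max(s − 50, 0)` and then standardized, so the
fitted exposure-response curve is continuous at the knot), physical activity
(g), time of day (morning baseline), day of week (Monday baseline), age group
(5 levels, <30 baseline), BMI group (4 levels, <25 baseline), and gender.
Random effects z per participant: intercept, both hinge sound slopes, and
activity. Moderators enter only as fixed two-way interactions
moderator × hinge-term.

Priors: half-Cauchy(0, 2.5) on every SD, Normal(0, 5²) on everything else.
On standardized data these are weakly informative; the exact scales used in
the original analyses of this model family are not published, and a
sensitivity factor of 2 either way does not move the posterior means of the
sound effects at the default cohort sizes.

### Sampling

Sampling is Hamiltonian Monte Carlo written for this package (no
probabilistic-programming backend is required): leapfrog integration with a
jittered number of steps (uniform on 1..32), dual-averaging step-size
adaptation to a 0.95 target acceptance rate, windowed diagonal mass-matrix
estimation during warmup, and divergence detection at an energy error of
1000. Random effects are non-centered (γ = μ + σ·u, u ~ N(0,1)); the
fixed-effects block is internally whitened with a thin QR decomposition so a
diagonal mass matrix suffices, and the draws are mapped back to the design
scale. Gradients of the log posterior are exact (hand-derived; verified
against finite differences in the test suite). Defaults: 4 chains ×
(1000 warmup + 1000 draws) at full scale; the test suite and acceptance
script use 4 × (500+500), which passes the validation checks (split-R-hat
< 1.1 on every reported parameter and zero divergences) on the default
cohorts. Identical seeds give identical draws.

Posterior summaries report the mean and the 90% credible interval (5th-95th
percentile of pooled post-warmup draws), R-hat and effective sample size per
parameter.

### Effect translation

With input and outcomes standardized, a sound coefficient is the SD change
in latent wellbeing per SD of sound. The percent change per Δ dBA is
`100 · (Δ / SD_sound) · coef`; with the study dispersion of 8.79 dBA and
Δ = 10, the below-knot coefficient 0.0471 gives +5.4% and the above-knot
coefficient −0.0167 gives −1.9%, applied draw-wise to obtain credible
intervals. Whether such interval labels are 90% or 95% is ambiguous in this
model family's reporting; both are returned.

## Synthetic cohorts

The generator draws what the model assumes, plus controlled corruption:

- **Participants** (defaults echo a 231-worker office cohort): age
  ~ N(44.15, 12.22²) truncated to [18, 80]; BMI ~ N(27.60, 6.10²) truncated
  to [15, 50]; 49.78% female; binary traits (high blood pressure, anxiety,
  computer-use-intensive work, sleep problems, managerial/meeting-intensive/
  technical work) Bernoulli with configurable prevalences; neuroticism and
  noise sensitivity standard-normal survey scores. About 3.5% of
  participants contribute only two of the three days.
- **Sound** ~ truncated normal on [30, 80] dBA; the underlying scale is
  solved numerically so the *truncated* SD equals the configured 8.79 dBA.
  The marginal shape is an assumption — only the dispersion is known.
- **Activity** ~ lognormal (median ≈ 0.03 g), typical of seated office work.
- **Latent score and outcomes** follow the model above with the published
  posterior means as default truth (sound +0.0471/−0.0167, activity 0.2756,
  the full covariate table), λ₂ = 0.8 and σ₁ = σ₂ = 0.9 — chosen so that
  roughly 20% of standardized outcome variance is structured, consistent
  with holdout errors near 0.9 SD. SDNN is mapped to ms as 50 + 20·y₁; the
  normalized-HF score is squashed into (0,1) by a logistic with slope 0.5
  (the analysis re-standardizes it, so the squash affects realism, not
  inference, beyond mild tail attenuation).
- **Heterogeneity**: each participant's sound-slope deviation is
  Σ_p β_p x_pj + ε_j, ε_j ~ N(0, σ_r²), evaluated separately for the two
  hinge segments; intercept and activity deviations are zero-mean normals
  (SD 0.30 and 0.10). `sigma_gamma_sound` documents the slope dispersion the
  fitted model assumes; generation of the sound slopes is governed entirely
  by the heterogeneity equation so that planted moderator effects are exact.
- **Corruption**: each channel independently missing at 2%; 0.5% of outcome
  cells multiplied by 5, which guarantees they exceed the 99.5th percentile
  in realistic cohorts.
- Time of day splits each day's bins 40/40/20 into morning/afternoon/evening
  (an office-day shape; not dictated by the study design); wear periods
  start on any weekday and wrap over weekends.

What the generator does **not** emulate: raw R-R series and HRV computation,
sound spectra or sound types, autocorrelated within-day exposure, non-normal
HRV noise, informative missingness, device artifacts. Passing recovery tests
therefore shows the estimators are correct under the assumed model, not that
the model is right for any particular building's data.

## Preprocessing

Fixed order, each stage logging row counts: 5-minute aggregation
(within-bin means per channel) → drop epochs missing either outcome →
drop epochs with either outcome strictly above its own 99.5th percentile
(per-outcome OR rule; skipped with a warning under 200 rows) → exclude
participants with under 12 epochs (one hour) → mean-impute missing inputs
(means from training days only) → discretize age/BMI (left-closed bins, the
top bin strictly above its edge: BMI 35.0 → "30-35") → split days 1-2 /
day 3 → standardize inputs and outcomes with training-split parameters.
Percentile filtering precedes the short-participant exclusion so outliers
cannot rescue a short record.

## Pilot models and the optimal sound level

Per-outcome linear mixed models (random intercept + random sound slope,
ML-fit so AICs compare) with an optional quadratic sound term; a singular
random-effects covariance triggers an intercept-only refit, and a boundary
variance degenerates to OLS, both flagged. AIC comparison prefers the lower
value, with ties (<1e-9) to the simpler model.

The optimal-sound estimator works on the stacked standardized outcomes
(univariate transformation with an outcome indicator). A cubic penalized
B-spline of raw sound (12 basis functions, second-difference penalty chosen
by GCV, participant intercepts absorbed exactly by within-participant
demeaning) supplies the fitted curve and a flat/monotone diagnosis via its
argmax on a 0.1-dBA grid. For the point estimate, the curve argmax is
refined by a free-knot hinge fit (profile RSS over a 0.1-dBA knot grid):
with a weak above-knot slope, any smooth's argmax is displaced toward the
flatter side and has high variance, whereas the hinge fit pools all data on
each side of the candidate knot — in replicate simulations at the default
truth it is unbiased (mean 50.1, SD 1.3 dBA at 400 participants). The
bootstrap interval resamples participants (200 seeded replicates by
default).

## Heterogeneity selection

Step 1 refits the latent model on the below-50 and at-or-above-50 dBA
subsets (selected on raw dBA) with *only* varying coefficients — intercept,
the subset's hinge sound term, activity — whose means are estimated
(non-zero-mean random effects). Person-level variables are excluded here
because they are constant within participant. Per-participant posterior
mean slopes (participants with fewer than 5 epochs in the subset omitted)
become the outcome of step 2: lasso, elastic net (mixing 0.5) and adaptive
lasso (weights = 1/|OLS coefficient|, capped at 1e6) regressions on 12
person-level variables (age and BMI group dummies, the seven binary traits,
neuroticism, noise sensitivity, average sound exposure — no gender).
Penalties are tuned on a 50-point log grid by 5-fold seeded
cross-validation using the one-standard-error rule — the usual sparser
choice when the goal is selection rather than prediction; the MSE-minimizing
rule is available as an option. The consensus set is the variables non-zero
(|coef| > 1e-8) under all three methods, treated per dummy level. The
optional slope-SD-weighted step-2 variant is deliberately off by default:
the slope regression treats its residual as homoscedastic.

Shrinkage note: posterior-mean slopes are shrunk toward their subset mean by
a factor κ = τ²/(τ² + SE²), where SE is the per-participant slope
standard error (≈ 0.9/√(2·n_epochs) on the standardized scale). Step-2
coefficients are therefore attenuated by roughly κ relative to the planted
values — selection (support recovery) is unaffected because signal and noise
shrink together, but the printed coefficient magnitudes are not estimates of
the generating β_p. Exact support recovery further requires the planted
signal to clear the maximum noise t-statistic (~2.2 with 14 candidate
predictors), i.e. slope moderation of roughly ±0.1 at 200 participants and
~120 epochs each; smaller planted effects are detectable but not exactly
selectable, and the tests reflect that distinction.

## Evaluation

Holdout metrics (RMSE, MAPE with zero-actual rows excluded and counted) are
computed strictly on day-3 rows, on natural scales (SDNN in ms; nHF in its
(0,1) units, where actuals are never zero). The univariate-transformation
comparator stacks both standardized outcomes with one shared coefficient
vector, an outcome-indicator shift and a participant random intercept, then
refits with rows rescaled by inverse per-outcome residual SDs (an exact
heteroscedastic weighting; statsmodels MixedLM has no native weights).
Moderator-set comparison fits the latent model with no / all / consensus
moderators plus the comparator. The adjusted group-means table averages the
posterior-mean fixed-effects-only latent score (random effects removed) over
the rows of each sound range (≤45, (45,55], >55 dBA) per sub-population —
marginal means over the observed covariate grid, which is the reference-grid
choice documented here.

## Problem sizes and replicate counts

Defaults in the tests and the acceptance script are the package's study
conditions: parameter recovery uses 40 participants × ~150 epochs with
4 × (500+500) HMC draws (median over 10 replicate seeds for the activity
effect); generator fidelity uses ~30,000 epochs; the optimal-sound check
uses 800 participants (the breakpoint SE scales as n^(-1/2) and ±2 dBA
resolution needs that pooling); heterogeneity selection uses 200
participants × 120 epochs with 2 × (300+300)-draw subset fits. Recovery
tolerances of ±0.03 absorb the small attenuation (~5%) introduced by
re-standardizing outcomes whose generated variance slightly exceeds 1 and by
mean imputation of missing inputs.

## Known limitations

- The sampler is plain jittered-trajectory HMC, not NUTS; very small or very
  unbalanced cohorts can need more leapfrog steps (`max_leapfrog`) or a
  higher `target_accept` to pass the R-hat check.
- λ₂'s sign is data-identified; with near-zero λ₂ the two-outcome model
  degenerates gracefully but the heterogeneity step loses most of its
  information about normalized-HF.
- The EMM table uses observed-grid averaging; populations with strongly
  different covariate mixes across sound ranges confound range and covariate
  effects, exactly as in any observed-grid marginal mean.
- MAPE on SDNN in ms is scale-dependent; comparisons are only meaningful
  within a fixed standardization.
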