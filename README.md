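# soundwell

Office workers' physiological wellbeing responds to ambient sound, but the
two standard wearable-derived markers — SDNN (overall heart-rate-variability,
ms) and normalized-HF (parasympathetic modulation, unitless) — are noisy,
partially redundant views of the same underlying state. `soundwell` models
that state directly: a hierarchical Bayesian latent-variable model in which
one latent *physiological wellbeing* score drives both HRV outcomes and
responds piecewise-linearly to A-weighted sound level with a knot at 50 dBA.
It is built for methodologists and workplace-health researchers who want the
full analysis — simulation, preprocessing, estimation, individual-level
heterogeneity selection, and holdout evaluation — as tested, reusable code.

## The model

For participant *j*, 5-minute epoch *i*, outcome *h* ∈ {SDNN, nHF}
(standardized):

```
y_hij = λ_h · η_ij + ε_ij^(h),                 ε_ij^(h) ~ N(0, σ_h²)
η_ij  = β₀ + γ₀j + Σ_k β_k x_kij + Σ_m γ_mj z_mij
γ₀j ~ N(0, σ_γ₀²),  γ_mj ~ N(0, σ_γm²),        λ₁ ≡ 1
```

The sound effect enters through two standardized hinge terms,
`min(s, 50)` and `max(s − 50, 0)`, so the exposure-response curve is
continuous at the knot with separate slopes below and above it. Random
effects per participant: intercept, both sound slopes, activity. Error SDs
get half-Cauchy(2.5) priors, everything else Normal(0, 5²). Sampling is
Hamiltonian Monte Carlo (4 chains, non-centered random effects, exact
hand-derived gradients), validated by split-R-hat < 1.1 and a
zero-divergence check.

Because everything is standardized, a sound coefficient converts to a
percent wellbeing change per 10 dBA as `100 · (10 / SD_sound) · coef`.

Individual heterogeneity is analyzed in two steps: refit the model on the
below-/above-knot data subsets with non-zero-mean random coefficients only,
then regress each participant's posterior-mean sound slope on twelve
person-level variables with lasso, elastic net and adaptive lasso; variables
non-zero under all three form the consensus moderator set.

No study data ships with the package: the `cohort` module generates
synthetic wearable streams from exactly this model (sound SD 8.79 dBA,
published effect sizes as default truth), so every stage is testable offline.

## Worked example

```python
import soundwell as sw
from soundwell.latent import LatentWellbeingModel

profiles, effects, obs = sw.generate_cohort(40, days=3, bins_per_day=50, seed=1)
train, holdout, params, log = sw.run_preprocessing(obs, profiles)

model = LatentWellbeingModel.from_design(train)
res = model.fit(draws=500, warmup=500, chains=4, seed=11)
print(res.check_convergence())
print(res.summary().loc[["beta[sound_low]", "beta[sound_high]",
                         "beta[activity]", "lambda2"],
                        ["mean", "ci5", "ci95", "rhat"]].round(4))
eff = res.unstandardize_effect("sound_low", params.sds["sound"])
print(f"below-knot effect: {eff['mean']:+.1f}% per 10 dBA "
      f"(90% CrI {eff['ci90'][0]:+.1f} to {eff['ci90'][1]:+.1f})")
```

prints

```
convergence PASS: max R-hat 1.0602, 0 divergences, min ESS 68
                    mean     ci5    ci95    rhat
parameter
beta[sound_low]   0.0440  0.0134  0.0725  1.0064
beta[sound_high] -0.0216 -0.0446  0.0011  1.0063
beta[activity]    0.2540  0.2196  0.2878  1.0063
lambda2           0.7935  0.7350  0.8589  1.0058
below-knot effect: +5.1% per 10 dBA (90% CrI +1.5 to +8.3)
```

The cohort was generated with true standardized slopes +0.0471 below and
−0.0167 above the knot, activity 0.2756 and λ₂ = 0.8: the posterior means
recover each within ±0.03, and the translated below-knot effect (+5.1% per
10 dBA here) matches the +5.4% implied by the generating coefficient at the
study's 8.79-dBA sound dispersion. `sound_high`'s interval brushing zero at
40 participants is expected — the above-knot slope is the weakest signal in
the model.

A full pipeline run (simulate → preprocess → pilot → fit → heterogeneity →
evaluate → report, one seeded run directory with CSV/JSON artifacts and
SVG figures):

```
soundwell run-all --out runs/demo --seed 7
soundwell report --run-dir runs/demo
```

Each stage is also exposed individually (`soundwell simulate`, `preprocess`,
`pilot`, `fit`, `heterogeneity`, `evaluate`) against the same run directory.

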