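"""Two-step heterogeneity analysis of the sound-wellbeing association.

Step 1 fits, separately on the below-50-dBA and at-or-above-50-dBA data
subsets, a latent-outcome model whose predictor contains only participant
varying coefficients (intercept, sound slope, activity slope) with estimated
non-zero means — person-level variables are excluded because they are
constant within participant.  Step 2 regresses each participant's posterior
mean sound slope on the person-level variables with three penalized methods
(lasso, elastic net with mixing 0.5, adaptive lasso with weights from an
unpenalized fit), each tuned by seeded cross-validated grid search; the
consensus moderator set is the variables non-zero under all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression
from sklearn.model_selection import KFold

from .binning import AGE_LEVELS, BMI_LEVELS
from .latent import LatentWellbeingModel, LatentWellbeingResults, ModelSpec
from .preprocessing import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fit_subset_random_model",
    "extract_slopes",
    "person_design",
    "fit_regularized",
    "consensus_select",
    "SelectionResult",
    "moderator_refit",
    "NONZERO_TOL",
]

NONZERO_TOL = 1e-8
SUBSETS = ("below_50", "above_50")

#: person-level predictors of the step-2 slope regressions (dummy levels
#: for the discretized age/BMI groups; no gender)
PERSON_PREDICTORS = (
    ["neuroticism", "noise_sensitivity"]
    + AGE_LEVELS[1:]
    + BMI_LEVELS[1:]
    + ["high_bp", "anxiety", "sleep_problems", "cui_work", "managerial",
       "meeting_intensive", "technical", "avg_sound_exposure"]
)


def _subset_frame(design: DesignMatrix, subset: str) -> pd.DataFrame:
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    raw = design.frame["sound_dba"].to_numpy(float)
    mask = raw < design.params.knot if subset == "below_50" else raw >= design.params.knot
    return design.frame.loc[mask]


def fit_subset_random_model(design: DesignMatrix, subset: str,
                            draws: int = 500, warmup: int = 500,
                            chains: int = 4, seed: int = 0,
                            min_participants: int = 10) -> LatentWellbeingResults:
    """Step-1 fit on one sound-range subset (selected on raw dBA).

    The sound term is the hinge segment that varies within the subset
    (``sound_low`` below the knot, ``sound_high`` at or above it).
    """
    df = _subset_frame(design, subset)
    n_part = df["participant_id"].nunique()
    if n_part < min_participants:
        raise ValueError(
            f"subset {subset!r} has {n_part} participants (<{min_participants}); fit refused")
    sound_col = "sound_low" if subset == "below_50" else "sound_high"
    spec = ModelSpec(fixed_effects=[], random_effects=["const", sound_col, "activity"],
                     random_means=True)
    sub_design = DesignMatrix(df, design.params, design.participants)
    model = LatentWellbeingModel.from_design(sub_design, spec)
    res = model.fit(draws=draws, warmup=warmup, chains=chains, seed=seed)
    res.subset = subset
    res.sound_term = sound_col
    return res


def extract_slopes(results: LatentWellbeingResults, subset: str,
                   design: DesignMatrix | None = None,
                   min_obs: int = 5) -> pd.DataFrame:
    """Per-participant posterior mean and SD of the sound slope.

    Participants with fewer than ``min_obs`` epochs in the subset are
    omitted (their slope is prior-dominated); omissions are logged.
    """
    sound_col = getattr(results, "sound_term",
                        "sound_low" if subset == "below_50" else "sound_high")
    table = results.random_effect_table()
    table = table.loc[table["term"] == sound_col].drop(columns="term")
    counts = np.bincount(results.model.groups, minlength=results.model.J)
    n_obs = pd.Series(counts, index=results.model.participants)
    if design is not None:
        sub = _subset_frame(design, subset)
        n_obs = sub.groupby("participant_id").size().reindex(
            results.model.participants, fill_value=0)
    table["n_obs"] = n_obs.reindex(table["participant_id"]).to_numpy()
    dropped = table.loc[table["n_obs"] < min_obs, "participant_id"].tolist()
    if dropped:
        logger.info("extract_slopes(%s): omitting %d participants with <%d obs",
                    subset, len(dropped), min_obs)
    table = table.loc[table["n_obs"] >= min_obs].reset_index(drop=True)
    table["subset"] = subset
    return table.rename(columns={"mean": "slope_mean", "sd": "slope_sd"})


def person_design(profiles: pd.DataFrame) -> pd.DataFrame:
    """Person-level predictor matrix (one row per participant), dummy-coded
    with 'below 30' / 'below 25' baselines."""
    df = profiles.set_index("participant_id")
    out = pd.DataFrame(index=df.index)
    out["neuroticism"] = df["neuroticism"].astype(float)
    out["noise_sensitivity"] = df["noise_sensitivity"].astype(float)
    for lev in AGE_LEVELS[1:]:
        out[lev] = (df["age_group"] == lev).astype(float)
    for lev in BMI_LEVELS[1:]:
        out[lev] = (df["bmi_group"] == lev).astype(float)
    for flag in ["high_bp", "anxiety", "sleep_problems", "cui_work",
                 "managerial", "meeting_intensive", "technical"]:
        out[flag] = df[flag].astype(float)
    out["avg_sound_exposure"] = df["avg_sound_exposure"].astype(float)
    return out


@dataclass
class RegularizedFit:
    method: str
    coef: pd.Series           # original dummy scale
    intercept: float
    alpha: float
    cv_mse: float
    capped_weights: list = field(default_factory=list)

    @property
    def support(self) -> set:
        return set(self.coef.index[self.coef.abs() > NONZERO_TOL])


def _cv_alpha(Xs, y, make_est, grid, cv_folds, seed, rule="1se"):
    """Cross-validated penalty choice.

    ``rule='min'`` takes the MSE-minimizing penalty; ``rule='1se'`` (default)
    takes the largest penalty whose CV MSE is within one standard error of
    the minimum — the usual sparser choice for selection-oriented fits.
    """
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    grid = sorted(grid)
    mses, ses = [], []
    for alpha in grid:
        errs = []
        for itr, ite in kf.split(Xs):
            est = make_est(alpha)
            est.fit(Xs[itr], y[itr])
            r = y[ite] - est.predict(Xs[ite])
            errs.append(float(r @ r) / len(ite))
        mses.append(float(np.mean(errs)))
        ses.append(float(np.std(errs, ddof=1) / np.sqrt(len(errs))))
    k_min = int(np.argmin(mses))
    if rule == "min":
        return grid[k_min], mses[k_min]
    cutoff = mses[k_min] + ses[k_min]
    eligible = [k for k in range(k_min, len(grid)) if mses[k] <= cutoff]
    k = max(eligible)
    return grid[k], mses[k]


def fit_regularized(slopes: pd.DataFrame, profiles: pd.DataFrame, method: str,
                    cv_folds: int = 5, grid=None, seed: int = 0,
                    rule: str = "1se") -> RegularizedFit:
    """Penalized regression of participant slopes on person-level variables.

    Predictors are standardized internally; coefficients are reported on the
    original (dummy) scale.  The penalty is chosen on a log grid by
    cross-validated MSE at the participant level.  ``method`` is one of
    'lasso', 'elasticnet', 'adaptive_lasso'.  A penalty of exactly zero falls
    back to ordinary least squares.
    """
    if method not in ("lasso", "elasticnet", "adaptive_lasso"):
        raise ValueError(f"unknown method {method!r}")
    X = person_design(profiles).loc[slopes["participant_id"]]
    names = list(X.columns)
    y = slopes["slope_mean"].to_numpy(float)
    Xv = X.to_numpy(float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd

    capped = []
    if method == "adaptive_lasso":
        ols = LinearRegression().fit(Xs, y)
        w = np.abs(ols.coef_)
        capped = [names[i] for i in np.nonzero(w < 1e-12)[0]]
        weights = np.minimum(1.0 / np.maximum(w, 1e-300), 1e6)
        Xw = Xs / weights  # column rescale: lasso on Xw == weighted-l1 on Xs
    else:
        weights = np.ones(Xs.shape[1])
        Xw = Xs

    if grid is None:
        alpha_max = float(np.max(np.abs(Xw.T @ (y - y.mean())))) / len(y)
        alpha_max = max(alpha_max, 1e-12)
        grid = alpha_max * np.logspace(-4, 0, 50)

    def make_est(alpha):
        if alpha < 1e-12:
            return LinearRegression()
        if method == "elasticnet":
            return ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=50000)
        return Lasso(alpha=alpha, max_iter=50000)

    alpha, cv_mse = _cv_alpha(Xw, y, make_est, list(grid), cv_folds, seed, rule=rule)
    est = make_est(alpha).fit(Xw, y)
    coef_std = est.coef_ / weights          # back from the weight rescale
    coef = pd.Series(coef_std / sd, index=names, name=method)
    intercept = float(est.intercept_ - np.sum(coef_std * mu / sd))
    return RegularizedFit(method, coef, intercept, float(alpha), cv_mse, capped)


@dataclass
class SelectionResult:
    """Per-method coefficient vectors and the consensus support set."""

    fits: dict                  # method -> RegularizedFit
    consensus: list             # variables non-zero in all methods

    def to_table(self) -> pd.DataFrame:
        """Coefficient table (variables x methods); zeros shown blank."""
        df = pd.DataFrame({m: f.coef for m, f in self.fits.items()})
        return df.where(df.abs() > NONZERO_TOL)


def consensus_select(fits) -> SelectionResult:
    """Intersection of the non-zero supports of the supplied fits.

    Dummy-coded factors are treated per level, as each level carries its own
    coefficient.
    """
    fits = {f.method: f for f in fits} if not isinstance(fits, dict) else fits
    supports = [f.support for f in fits.values()]
    consensus = set.intersection(*supports) if supports else set()
    order = next(iter(fits.values())).coef.index if fits else []
    return SelectionResult(fits, [v for v in order if v in consensus])


def select_moderators(design: DesignMatrix, profiles: pd.DataFrame,
                      subsets=SUBSETS, draws: int = 500, warmup: int = 500,
                      chains: int = 4, seed: int = 0, cv_folds: int = 5,
                      min_participants: int = 10, rule: str = "1se") -> dict:
    """Full two-step pipeline; returns per-subset SelectionResults and the
    union consensus variable list."""
    out = {"subsets": {}, "consensus_union": []}
    union: list = []
    for i, subset in enumerate(subsets):
        res = fit_subset_random_model(design, subset, draws=draws, warmup=warmup,
                                      chains=chains, seed=seed + i,
                                      min_participants=min_participants)
        slopes = extract_slopes(res, subset, design=design)
        fits = [fit_regularized(slopes, profiles, m, cv_folds=cv_folds, seed=seed,
                                rule=rule)
                for m in ("lasso", "elasticnet", "adaptive_lasso")]
        sel = consensus_select(fits)
        out["subsets"][subset] = {"selection": sel, "slopes": slopes,
                                  "convergence": res.check_convergence()}
        union += [v for v in sel.consensus if v not in union]
    out["consensus_union"] = union
    return out


def moderator_refit(design: DesignMatrix, moderators, draws: int = 500,
                    warmup: int = 500, chains: int = 4, seed: int = 0,
                    sound_grid: np.ndarray | None = None):
    """Refit the population latent model with moderator x hinge interactions.

    Returns ``(results, curves)`` where curves tabulates the predicted
    latent-wellbeing-vs-sound profile per moderator group (the interaction
    plot): for each binary moderator, the fixed-effect sound response with
    the moderator at 0 and at 1, all other covariates at baseline.
    """
    spec = ModelSpec(moderators=list(moderators))
    model = LatentWellbeingModel.from_design(design, spec)
    results = model.fit(draws=draws, warmup=warmup, chains=chains, seed=seed)

    params = design.params
    if sound_grid is None:
        raw = design.frame["sound_dba"].to_numpy(float)
        sound_grid = np.arange(np.floor(raw.min()), np.ceil(raw.max()) + 0.5, 0.5)
    h_low = params.transform("sound_low", np.minimum(sound_grid, params.knot))
    h_high = params.transform("sound_high", np.maximum(sound_grid - params.knot, 0.0))
    beta = {n: results.coef(n) for n in results.model.fixed_names}
    rows = []
    for mod in (list(moderators) or [None]):
        for level in ((0.0, 1.0) if mod is not None else (None,)):
            theta = (beta.get("sound_low", 0.0) * h_low
                     + beta.get("sound_high", 0.0) * h_high)
            if mod is not None and level == 1.0:
                theta = theta + (beta.get(f"{mod}:sound_low", 0.0) * h_low
                                 + beta.get(f"{mod}:sound_high", 0.0) * h_high)
            for s, t in zip(sound_grid, theta):
                rows.append({"moderator": mod if mod is not None else "(none)",
                             "level": level if level is not None else np.nan,
                             "sound_dba": float(s), "wellbeing": float(t)})
    return results, pd.DataFrame(rows)
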