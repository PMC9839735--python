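"""Holdout evaluation: prediction metrics, the univariate-transformation
comparator, moderator-set comparison, and adjusted group means.

Metrics are computed strictly on the day-3 holdout split.  The comparator
stacks the two standardized outcomes into one response with a shared set of
input coefficients and outcome-specific residual variances (two-pass
inverse-variance weighting), the classical simultaneous-modeling approach
the latent model is benchmarked against.  The adjusted-means table reports
the fixed-effects-only posterior-mean latent score (random effects removed)
averaged over sound-range cells, per sub-population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .latent import LatentWellbeingModel, LatentWellbeingResults, ModelSpec
from .preprocessing import FIXED_EFFECT_COLUMNS, DesignMatrix

__all__ = [
    "compute_metrics",
    "fit_univariate_comparator",
    "compare_moderator_sets",
    "emm_group_table",
    "SOUND_RANGES",
]

#: post-hoc sound ranges (dBA): <=45, (45, 55], >55
SOUND_RANGES = ((-np.inf, 45.0), (45.0, 55.0), (55.0, np.inf))
RANGE_LABELS = ("<=45", "(45,55]", ">55")


def compute_metrics(pred, actual):
    """RMSE and MAPE (%) of predictions.

    Rows with ``actual == 0`` are excluded from MAPE and counted.
    Returns ``(rmse, mape, n_zero_excluded)``.
    """
    p = np.asarray(pred, float)
    a = np.asarray(actual, float)
    if p.shape != a.shape:
        raise ValueError("pred and actual must have equal length")
    rmse = float(np.sqrt(np.mean((p - a) ** 2)))
    nz = a != 0
    mape = float(100.0 * np.mean(np.abs(p[nz] - a[nz]) / np.abs(a[nz])))
    return rmse, mape, int((~nz).sum())


def _assert_holdout(train: DesignMatrix, holdout: DesignMatrix):
    """Guard against leaking training rows into the metric set."""
    if "day_index" in train.frame.columns and "day_index" in holdout.frame.columns:
        if (holdout.frame["day_index"] <= 2).any():
            raise ValueError("holdout contains training-day rows")


def metrics_frame(pred: pd.DataFrame, holdout: DesignMatrix, model_name: str) -> pd.DataFrame:
    """Per-outcome natural-scale metrics for one prediction table."""
    params = holdout.params
    actual_sdnn = params.inverse("sdnn", holdout.frame["y1"].to_numpy(float))
    actual_nhf = params.inverse("nhf", holdout.frame["y2"].to_numpy(float))
    rows = []
    for outcome, a, p in (("sdnn", actual_sdnn, pred["sdnn_ms"]),
                          ("nhf", actual_nhf, pred["nhf"])):
        rmse, mape, nzero = compute_metrics(p, a)
        rows.append({"model": model_name, "outcome": outcome,
                     "rmse": rmse, "mape": mape, "n_zero_excluded": nzero})
    return pd.DataFrame(rows)


@dataclass
class UnivariateComparatorFit:
    params: pd.Series
    columns: list
    sigma_by_outcome: tuple
    result: object

    def predict(self, design: DesignMatrix) -> pd.DataFrame:
        df = design.frame
        preds = {}
        try:
            re = self.result.random_effects
        except (np.linalg.LinAlgError, ValueError, AttributeError):
            re = {}
        gamma0 = df["participant_id"].map(
            lambda p: float(re[p].iloc[0]) if p in re else 0.0).to_numpy()
        for h, (ycol, out) in enumerate((("y1", "sdnn"), ("y2", "nhf"))):
            X = _stack_design(df, outcome2=float(h)).reindex(
                columns=self.columns, fill_value=0.0)
            mu = X.to_numpy() @ self.params.to_numpy() + gamma0
            preds[f"pred_{ycol}"] = mu
            preds["sdnn_ms" if out == "sdnn" else "nhf"] = design.params.inverse(
                "sdnn" if out == "sdnn" else "nhf", mu)
        return pd.DataFrame(preds, index=df.index)


def _stack_design(df: pd.DataFrame, outcome2: float) -> pd.DataFrame:
    from .pilot import full_rank_design

    X = df[list(FIXED_EFFECT_COLUMNS)].astype(float).copy()
    X.insert(0, "const", 1.0)
    X = full_rank_design(X)
    X["outcome2"] = outcome2
    return X


def fit_univariate_comparator(train: DesignMatrix,
                              outcomes=("y1", "y2")) -> UnivariateComparatorFit:
    """Simultaneous model via univariate transformation of the two outcomes.

    The standardized outcomes are stacked into one response with a common
    input-coefficient vector and an outcome-indicator intercept shift; a
    participant random intercept captures within-person correlation.  After a
    first ML fit, per-outcome residual variances are estimated and the model
    is refit with rows rescaled by the inverse residual SDs (accounting for
    heteroscedastic outcome errors).  With a single outcome the stacking is
    vacuous and the fit reduces to the plain mixed model.
    """
    df = train.frame
    X = pd.concat([_stack_design(df, float(h)) for h in range(len(outcomes))],
                  ignore_index=True)
    if len(outcomes) == 1:
        X = X.drop(columns="outcome2")
    y = np.concatenate([df[o].to_numpy(float) for o in outcomes])
    groups = np.tile(df["participant_id"].to_numpy(), len(outcomes))
    which = np.repeat(np.arange(len(outcomes)), len(df))

    def _fit(Xf, yf, re):
        mod = sm.regression.mixed_linear_model.MixedLM(yf, Xf, groups,
                                                       exog_re=re.reshape(-1, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return mod.fit(reml=False)
            except np.linalg.LinAlgError:
                # RE variance on the boundary: degenerate to (weighted) OLS
                res = sm.OLS(yf, Xf).fit()
                res.fe_params = res.params
                return res

    res1 = _fit(X, y, np.ones(len(y)))
    try:
        fitted_vals = np.asarray(res1.fittedvalues)
    except (np.linalg.LinAlgError, ValueError):
        # singular RE covariance (variance on the boundary): fixed part only
        fitted_vals = X.to_numpy() @ res1.fe_params.to_numpy()
    resid = y - fitted_vals
    sig = np.array([np.std(resid[which == h], ddof=1)
                    for h in range(len(outcomes))])
    w = 1.0 / sig[which]
    # rescale response, design and random-effect column by the same weight:
    # equivalent to a heteroscedastic mixed model with the coefficients and
    # random intercepts kept on the original outcome scale
    res2 = _fit(X.mul(w, axis=0), y * w, w)
    return UnivariateComparatorFit(res2.fe_params, list(X.columns),
                                   tuple(float(s) for s in sig), res2)


def compare_moderator_sets(train: DesignMatrix, holdout: DesignMatrix,
                           consensus: list, all_moderators: list,
                           draws: int = 500, warmup: int = 500, chains: int = 4,
                           seed: int = 0) -> pd.DataFrame:
    """Holdout metrics for the latent model under three moderator sets
    (none / all person-level variables / consensus set), plus the
    univariate-transformation comparator."""
    _assert_holdout(train, holdout)
    tables = []
    for name, mods in (("latent_no_moderators", []),
                       ("latent_all_moderators", list(all_moderators)),
                       ("latent_consensus", list(consensus))):
        model = LatentWellbeingModel.from_design(train, ModelSpec(moderators=mods))
        res = model.fit(draws=draws, warmup=warmup, chains=chains, seed=seed)
        pred = res.predict(holdout)
        t = metrics_frame(pred, holdout, name)
        t["n_fixed_effects"] = model.p
        tables.append(t)
    comp = fit_univariate_comparator(train)
    t = metrics_frame(comp.predict(holdout), holdout, "univariate_comparator")
    t["n_fixed_effects"] = len(comp.params)
    tables.append(t)
    return pd.concat(tables, ignore_index=True)


def emm_group_table(design: DesignMatrix, results, strata: dict | None = None
                    ) -> pd.DataFrame:
    """Mean adjusted wellbeing score per sub-population and sound range.

    The adjusted score is the posterior-mean fixed-effects-only latent
    predictor (participant random effects subtracted), averaged over the
    rows falling in each range of raw sound level -- marginal means over the
    observed covariate grid.  ``results`` is either a fitted
    :class:`LatentWellbeingResults` or a {term: coefficient} mapping of
    posterior-mean fixed effects.
    """
    df = design.frame
    if isinstance(results, dict):
        from .latent import _term_column
        score = np.zeros(len(df))
        for name, b in results.items():
            score += float(b) * _term_column(df, name)
    else:
        score = results.fixed_predictor(design)
    sound = df["sound_dba"].to_numpy(float)
    groups = {"complete": np.ones(len(df), bool)}
    if strata:
        for name, sel in strata.items():
            mask = df[sel].to_numpy(float) > 0 if isinstance(sel, str) else np.asarray(sel, bool)
            groups[name] = mask
    rows = []
    for name, mask in groups.items():
        row = {"sub_population": name}
        for (lo, hi), lab in zip(SOUND_RANGES, RANGE_LABELS):
            cell = mask & (sound > lo) & (sound <= hi)
            row[lab] = float(score[cell].mean()) if cell.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sub_population")
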