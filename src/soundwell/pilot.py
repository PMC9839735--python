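"""Pilot analysis: per-outcome curvilinear mixed models and the optimal
sound level.

Each outcome (standardized SDNN or normalized-HF) gets an independent linear
mixed model with participant random intercept and random sound slope; the
curvilinear variant adds a quadratic sound term.  Models are fit by maximum
likelihood so AICs are comparable.  The optimal sound level comes from the
stacked (univariate-transformed) outcome: a penalized cubic B-spline smooth
of raw sound supplies the curve and flat/monotone diagnosis, and the point
estimate is refined by a free-knot hinge fit, with a participant-level
percentile bootstrap interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .preprocessing import (
    AGE_DUMMIES,
    BMI_DUMMIES,
    DOW_DUMMIES,
    TOD_DUMMIES,
    DesignMatrix,
)

__all__ = ["PilotFit", "fit_curvilinear_mixed", "compare_aic",
           "estimate_optimal_sound", "OptimalSoundEstimate"]

PILOT_COVARIATES = (TOD_DUMMIES + DOW_DUMMIES + AGE_DUMMIES + BMI_DUMMIES
                    + ["gender_female"])


@dataclass
class PilotFit:
    """One per-outcome mixed-model fit."""

    outcome: str
    quadratic: bool
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # 95% CI, columns [lower, upper]
    aic: float
    n_params: int
    re_cov: pd.DataFrame
    re_structure: str = "intercept+slope"  # or "intercept_only" after a singular refit
    converged: bool = True

    def __post_init__(self):
        if not np.isfinite(self.aic):
            raise ValueError("AIC must be finite")


def full_rank_design(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Drop collinear columns (pivoted QR) so mixed-model fits stay stable."""
    from scipy.linalg import qr

    A = X.to_numpy(float)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    keep = sorted(piv[d > tol * max(d[0], 1.0)])
    return X.iloc[:, keep]


def _design_frame(design: DesignMatrix, quadratic: bool, covariates=None):
    df = design.frame
    cols = ["sound_lin"] + (["sound_lin_sq"] if quadratic else [])
    cols += ["activity"]
    cols += list(covariates) if covariates is not None else list(PILOT_COVARIATES)
    X = df[cols].astype(float).copy()
    X.insert(0, "const", 1.0)
    # unpopulated dummy levels in small cohorts would make the design singular
    return full_rank_design(X)


def fit_curvilinear_mixed(design: DesignMatrix, outcome: str,
                          quadratic: bool = False, covariates=None) -> PilotFit:
    """Linear mixed model for one outcome with random intercept and random
    sound slope per participant, ML-fit (AIC-comparable).

    A singular random-effects covariance triggers a refit with
    intercept-only random effects, flagged on the result.
    """
    if outcome not in ("sdnn", "nhf"):
        raise ValueError("outcome must be 'sdnn' or 'nhf'")
    df = design.frame
    if design.n_participants < 2:
        raise ValueError("need at least 2 participants")
    y = df["y1" if outcome == "sdnn" else "y2"].to_numpy(float)
    X = _design_frame(design, quadratic, covariates)
    groups = df["participant_id"].to_numpy()
    exog_re = X[["const", "sound_lin"]]

    def _fit(re):
        mod = sm.regression.mixed_linear_model.MixedLM(y, X, groups, exog_re=re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mod.fit(reml=False)

    re_structure = "intercept+slope"
    try:
        res = _fit(exog_re)
        cov_re = np.asarray(res.cov_re)
        singular = (not res.converged) or np.linalg.cond(cov_re) > 1e8 or np.min(
            np.linalg.eigvalsh(cov_re)) <= 0
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        try:
            res = _fit(X[["const"]])
            re_structure = "intercept_only"
        except np.linalg.LinAlgError:
            res = None
    if singular and res is None:
        # intercept variance on the boundary at zero: the mixed model
        # degenerates to ordinary least squares
        ols = sm.OLS(y, X).fit()
        return PilotFit(
            outcome=outcome, quadratic=quadratic, params=ols.params,
            bse=ols.bse, conf_int=ols.conf_int(), aic=float(ols.aic),
            n_params=len(ols.params) + 1, re_cov=pd.DataFrame([[0.0]]),
            re_structure="none", converged=True)
    k = len(res.params)
    return PilotFit(
        outcome=outcome,
        quadratic=quadratic,
        params=res.fe_params,
        bse=res.bse[: len(res.fe_params)],
        conf_int=res.conf_int().iloc[: len(res.fe_params)],
        aic=float(res.aic),
        n_params=k,
        re_cov=pd.DataFrame(np.asarray(res.cov_re)),
        re_structure=re_structure,
        converged=bool(res.converged),
    )


def compare_aic(fit_a: PilotFit, fit_b: PilotFit):
    """Prefer the lower-AIC model; near-ties go to the simpler model.

    Returns ``(preferred_fit, delta_aic)`` with ``delta_aic = aic_a - aic_b``.
    """
    delta = fit_a.aic - fit_b.aic
    if abs(delta) < 1e-9:
        preferred = fit_a if fit_a.n_params <= fit_b.n_params else fit_b
    else:
        preferred = fit_a if delta < 0 else fit_b
    return preferred, float(delta)


@dataclass
class OptimalSoundEstimate:
    optimum_dba: float
    interval: tuple | None
    flat_or_monotone: bool
    grid: np.ndarray = field(repr=False, default=None)
    curve: np.ndarray = field(repr=False, default=None)


def _spline_basis(x, knots_x, df):
    """Cubic B-spline design over the observed sound range."""
    degree = 3
    n_inner = df - degree
    inner = np.quantile(knots_x, np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner > 0 else []
    lo, hi = knots_x.min(), knots_x.max()
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def _fit_stacked_spline(df_stack, spline_df, n_basis: int = 12):
    """Penalized-spline fit of the stacked outcome vs raw sound.

    Participant random intercepts are absorbed exactly by within-participant
    demeaning; the remaining problem is a ridge regression with a
    second-difference penalty on the B-spline coefficients, with the penalty
    weight chosen by generalized cross-validation.  Returns the spline
    coefficient vector (curve shape up to an additive constant).
    """
    sound = df_stack["sound_dba"].to_numpy(float)
    n_basis = max(n_basis, spline_df)
    B = _spline_basis(sound, sound, n_basis)
    cols, names = [B], []
    for extra in ("activity", "outcome2"):
        v = df_stack[extra].to_numpy(float)
        if np.ptp(v) > 0:
            cols.append(v[:, None])
            names.append(extra)
    A = np.column_stack(cols)
    y = df_stack["y"].to_numpy(float)

    grp = df_stack["participant_id"].to_numpy()
    gmean = pd.DataFrame(A).groupby(grp).transform("mean").to_numpy()
    A_dm = A - gmean
    y_dm = y - pd.Series(y).groupby(grp).transform("mean").to_numpy()

    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P0 = np.zeros((A.shape[1], A.shape[1]))
    P0[:k, :k] = D.T @ D
    AtA = A_dm.T @ A_dm
    Aty = A_dm.T @ y_dm
    n = len(y)
    ridge = 1e-8 * np.trace(AtA) / A.shape[1] * np.eye(A.shape[1])

    best = (np.inf, None)
    scale = np.trace(AtA[:k, :k]) / max(np.trace(P0), 1e-12)
    for lam in scale * np.logspace(-6, 4, 31):
        M = AtA + lam * P0 + ridge
        try:
            beta = np.linalg.solve(M, Aty)
            edf = float(np.trace(np.linalg.solve(M, AtA)))
        except np.linalg.LinAlgError:
            continue
        rss = float(y_dm @ y_dm - 2 * beta @ Aty + beta @ AtA @ beta)
        denom = max(n - edf - df_stack["participant_id"].nunique(), 1.0)
        gcv = n * rss / denom**2
        if gcv < best[0]:
            best = (gcv, beta)
    if best[1] is None:
        raise np.linalg.LinAlgError("penalized spline fit failed")
    return best[1], n_basis


def _curve_argmax(alpha, n_basis, sound_obs):
    grid = np.arange(sound_obs.min(), sound_obs.max() + 1e-9, 0.1)
    Bg = _spline_basis(grid, sound_obs, n_basis)
    curve = Bg @ alpha[: Bg.shape[1]]
    k = int(np.argmax(curve))
    return grid, curve, k


def _hinge_breakpoint(stack, step: float = 0.1):
    """Profile-RSS search for the extremum of a free-knot hinge fit.

    Within-participant demeaning absorbs random intercepts; for each
    candidate knot a continuous two-slope hinge (plus activity) is fit by
    least squares, and the RSS-minimizing knot is returned with its slopes.
    Pooling all data on each side of the knot locates the slope-sign change
    far more precisely than the argmax of a smooth.
    """
    sound = stack["sound_dba"].to_numpy(float)
    grp = stack["participant_id"].to_numpy()

    def demean(v):
        return v - pd.Series(v).groupby(grp).transform("mean").to_numpy()

    y_dm = demean(stack["y"].to_numpy(float))
    act_dm = demean(stack["activity"].to_numpy(float))
    lo, hi = np.percentile(sound, [5, 95])
    best = (np.inf, None, None)
    for k in np.arange(lo, hi + 1e-9, step):
        A = np.column_stack([demean(np.minimum(sound, k)),
                             demean(np.maximum(sound - k, 0.0)), act_dm])
        beta, *_ = np.linalg.lstsq(A, y_dm, rcond=None)
        r = y_dm - A @ beta
        rss = r @ r
        if rss < best[0]:
            best = (rss, float(k), beta)
    return best[1], best[2]


def estimate_optimal_sound(design: DesignMatrix, spline_df: int = 6,
                           n_boot: int = 200, seed: int = 0) -> OptimalSoundEstimate:
    """Optimal sound level for the stacked (univariate-transformed) outcome.

    A penalized B-spline smooth of raw sound supplies the fitted
    exposure-response curve and the flat/monotone diagnosis (grid argmax on
    a 0.1-dBA grid).  When the curve has an interior extremum, the point
    estimate is refined by a free-knot hinge fit (profile RSS over a 0.1-dBA
    knot grid), which is unbiased for the breakpoint where the smooth's
    argmax is dragged toward the flatter side.  The interval is a
    participant-level percentile bootstrap (None when ``n_boot == 0``).
    """
    df = design.frame
    if not (df["sound_dba"].min() < design.params.knot < df["sound_dba"].max()):
        raise ValueError("sound range must span the knot")
    base = df[["participant_id", "sound_dba", "activity"]]
    stack = pd.concat(
        [base.assign(y=df["y1"].to_numpy(float), outcome2=0.0),
         base.assign(y=df["y2"].to_numpy(float), outcome2=1.0)],
        ignore_index=True)

    def _estimate(data):
        alpha, n_basis = _fit_stacked_spline(data, spline_df)
        sound_obs = data["sound_dba"].to_numpy(float)
        grid, curve, k = _curve_argmax(alpha, n_basis, sound_obs)
        flat = (k == 0) or (k == len(grid) - 1) or (np.ptp(curve) < 1e-8)
        opt = float(grid[k])
        if not flat:
            knot, beta = _hinge_breakpoint(data)
            if beta is not None and beta[0] > 0 > beta[1]:
                opt = knot
        return opt, flat, grid, curve

    opt, flat, grid, curve = _estimate(stack)

    interval = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pids = stack["participant_id"].unique()
        by_pid = {p: g for p, g in stack.groupby("participant_id")}
        optima = []
        for b in range(n_boot):
            sel = rng.choice(pids, size=len(pids), replace=True)
            boot = pd.concat(
                [by_pid[p].assign(participant_id=f"{p}#{i}") for i, p in enumerate(sel)],
                ignore_index=True)
            try:
                optima.append(_estimate(boot)[0])
            except Exception:
                continue
        if optima:
            interval = (float(np.percentile(optima, 2.5)),
                        float(np.percentile(optima, 97.5)))

    return OptimalSoundEstimate(opt, interval, bool(flat), grid, curve)
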