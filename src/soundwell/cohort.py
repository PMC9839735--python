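"""Synthetic cohorts of office workers wearing sound and HRV monitors.

The generator draws data from exactly the model the downstream analysis
assumes: a single latent physiological-wellbeing variable driven by a
piecewise-linear (hinge) effect of A-weighted sound level with a knot at
50 dBA, plus physical activity, temporal and person-level covariates, and
participant-level random effects.  The two observed outcomes, SDNN and
normalized-HF, load on the latent variable with loadings ``lambda1``
(anchored positive) and ``lambda2``.

Heterogeneity in the sound slopes follows a person-level linear model: the
participant-specific slope deviation is ``sum_p beta_p * x_pj + eps_j`` with
``eps_j ~ N(0, sigma_r^2)``, so planted moderator effects can be recovered by
regressing generated slopes on person-level covariates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binning import age_group, bmi_group

__all__ = [
    "GeneratorTruth",
    "generate_participants",
    "generate_random_effects",
    "generate_observations",
    "generate_cohort",
    "OBSERVATION_COLUMNS",
]

#: canonical observation CSV schema (underscore-prefixed truth columns are
#: internal and dropped by :func:`write_observations`)
OBSERVATION_COLUMNS = [
    "participant_id",
    "day_index",
    "bin_index",
    "sound_dba",
    "activity_g",
    "sdnn_ms",
    "nhf",
    "time_of_day",
    "day_of_week",
]

WEEKDAYS = ["Mon", "Tue", "Wed", "Thu", "Fri"]

#: person-level variables eligible as heterogeneity moderators
PERSON_VARIABLES = [
    "neuroticism",
    "noise_sensitivity",
    "high_bp",
    "anxiety",
    "sleep_problems",
    "cui_work",
    "managerial",
    "meeting_intensive",
    "technical",
    "avg_sound_exposure",
    # age_group / bmi_group dummies are added level-wise
]


class ConfigError(ValueError):
    """Raised when a truth configuration references unknown variables."""


@dataclass
class GeneratorTruth:
    """Ground-truth parameters of the data-generating process.

    Defaults for the standardized fixed effects are the published
    posterior-mean estimates of the reference analysis, so parameter-recovery
    tests target realistic values.  All slope coefficients act on
    standardized predictors and produce the latent wellbeing score in
    standardized-outcome units.
    """

    # latent mixed-model fixed effects (standardized scale)
    beta0: float = 0.0
    beta_sound_low: float = 0.0471
    beta_sound_high: float = -0.0167
    beta_activity: float = 0.2756
    beta_time: tuple = (-0.1479, -0.0939)  # afternoon, evening (vs morning)
    beta_dow: tuple = (-0.1301, -0.0571, -0.0588, -0.0430)  # Tue..Fri vs Mon
    beta_age: tuple = (0.1361, -0.1468, -0.3119, -0.4413)  # vs below 30
    beta_bmi: tuple = (-0.2278, -0.3619, -0.6169)  # vs below 25
    beta_gender: float = -0.0439  # female vs male

    # outcome measurement layer
    lambda1: float = 1.0  # SDNN loading, sign/scale anchor
    lambda2: float = 0.8  # normalized-HF loading
    sigma1: float = 0.9
    sigma2: float = 0.9

    # participant-level random effects
    sigma_gamma0: float = 0.30
    sigma_gamma_sound: float = 0.05  # slope dispersion assumed by the fitted model
    sigma_gamma_act: float = 0.10

    # heterogeneity model for the sound slopes (applied to both hinge
    # segments; het_coeffs_high overrides the above-knot segment when given)
    het_coeffs: dict = field(default_factory=dict)
    het_coeffs_high: dict | None = None
    sigma_r: float = 0.05

    # exposure marginals
    sound_mean: float = 50.0
    sound_sd: float = 8.79
    sound_lo: float = 30.0
    sound_hi: float = 80.0
    knot: float = 50.0
    activity_logmean: float = -3.5  # median ~0.03 g
    activity_logsd: float = 0.6

    # natural-unit outcome mapping
    sdnn_mean_ms: float = 50.0
    sdnn_sd_ms: float = 20.0
    nhf_scale: float = 0.5  # logistic squash of the standardized score

    # person-level marginals
    age_mean: float = 44.15
    age_sd: float = 12.22
    bmi_mean: float = 27.60
    bmi_sd: float = 6.10
    p_female: float = 0.4978
    prevalences: dict = field(
        default_factory=lambda: {
            "high_bp": 0.25,
            "anxiety": 0.15,
            "cui_work": 0.50,
            "sleep_problems": 0.25,
            "managerial": 0.30,
            "meeting_intensive": 0.30,
            "technical": 0.30,
        }
    )
    two_day_fraction: float = 8.0 / 231.0

    # data corruption
    missing_rate: float = 0.02
    outlier_rate: float = 0.005

    seed: int = 0

    def __post_init__(self):
        if self.lambda1 <= 0:
            raise ConfigError("lambda1 must be positive (sign anchor)")
        for name in ("sound_sd", "sdnn_sd_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("sigma1", "sigma2", "sigma_gamma0", "sigma_gamma_sound",
                     "sigma_gamma_act", "sigma_r"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_rate", "outlier_rate"):
            if not 0.0 <= getattr(self, name) <= 0.2:
                raise ConfigError(f"{name} must be in [0, 0.2]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["beta_time"] = list(self.beta_time)
        d["beta_dow"] = list(self.beta_dow)
        d["beta_age"] = list(self.beta_age)
        d["beta_bmi"] = list(self.beta_bmi)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorTruth":
        d = json.loads(text)
        for key in ("beta_time", "beta_dow", "beta_age", "beta_bmi"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncnorm_scale_for_sd(target_sd, mean, lo, hi):
    """Underlying normal scale whose [lo, hi]-truncated SD equals target_sd."""

    def f(scale):
        a, b = (lo - mean) / scale, (hi - mean) / scale
        return stats.truncnorm.std(a, b, loc=mean, scale=scale) - target_sd

    return optimize.brentq(f, target_sd * 0.5, target_sd * 4.0, xtol=1e-10)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_participants(n: int, truth: GeneratorTruth, seed: int) -> pd.DataFrame:
    """Draw ``n`` participant profiles.

    Age and BMI are truncated normals matching the study cohort's marginals;
    survey traits are standard-normal scores; binary flags are Bernoulli with
    the configured prevalences.
    """
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n)))
    prof = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "age_years": _truncated_normal(rng, truth.age_mean, truth.age_sd, 18, 80, n),
            "bmi": _truncated_normal(rng, truth.bmi_mean, truth.bmi_sd, 15, 50, n),
            "gender": np.where(rng.random(n) < truth.p_female, "female", "male"),
            "neuroticism": rng.normal(0.0, 1.0, n),
            "noise_sensitivity": rng.normal(0.0, 1.0, n),
            "avg_sound_exposure": rng.normal(truth.sound_mean, 3.0, n),
        }
    )
    for flag, p in truth.prevalences.items():
        prof[flag] = rng.random(n) < p
    prof["age_group"] = age_group(prof["age_years"])
    prof["bmi_group"] = bmi_group(prof["bmi"])
    # wear periods start on any weekday and wrap over weekends (Thu, Fri, Mon)
    prof["start_dow"] = rng.integers(0, 5, n)
    prof["n_days"] = np.where(rng.random(n) < truth.two_day_fraction, 2, 3)
    return prof


def _person_design_value(profiles: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric column for a person-level variable or group-level dummy."""
    if name in profiles.columns:
        col = profiles[name]
        if col.dtype == bool:
            return col.to_numpy(float)
        if np.issubdtype(col.dtype, np.number):
            return col.to_numpy(float)
        raise ConfigError(f"person-level variable {name!r} is not numeric")
    # dummy levels, e.g. "age_50_60", "bmi_above_35", "gender_female"
    if name.startswith("age_"):
        return (profiles["age_group"] == name).to_numpy(float)
    if name.startswith("bmi_"):
        return (profiles["bmi_group"] == name).to_numpy(float)
    if name == "gender_female":
        return (profiles["gender"] == "female").to_numpy(float)
    raise ConfigError(f"unknown person-level variable {name!r} in het_coeffs")


def _het_shift(profiles: pd.DataFrame, coeffs: dict) -> np.ndarray:
    shift = np.zeros(len(profiles))
    for name, beta_p in coeffs.items():
        shift += beta_p * _person_design_value(profiles, name)
    return shift


def generate_random_effects(profiles: pd.DataFrame, truth: GeneratorTruth,
                            seed: int) -> pd.DataFrame:
    """Participant random effects: intercept, hinge sound slopes, activity.

    The sound-slope deviations follow the person-level heterogeneity model
    (systematic part from ``het_coeffs`` plus ``N(0, sigma_r^2)`` residual);
    intercept and activity deviations are zero-mean normals.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(profiles)
    low_coeffs = truth.het_coeffs
    high_coeffs = truth.het_coeffs_high if truth.het_coeffs_high is not None else low_coeffs
    eff = pd.DataFrame(
        {
            "participant_id": profiles["participant_id"].to_numpy(),
            "gamma0": rng.normal(0.0, truth.sigma_gamma0, n),
            "gamma_sound_low": _het_shift(profiles, low_coeffs)
            + (rng.normal(0.0, truth.sigma_r, n) if truth.sigma_r > 0 else 0.0),
            "gamma_sound_high": _het_shift(profiles, high_coeffs)
            + (rng.normal(0.0, truth.sigma_r, n) if truth.sigma_r > 0 else 0.0),
            "gamma_act": rng.normal(0.0, truth.sigma_gamma_act, n),
        }
    )
    return eff


def _time_of_day(bin_index: np.ndarray, bins_per_day: int) -> np.ndarray:
    """Deterministic 40/40/20 morning/afternoon/evening split of the day."""
    frac = bin_index / bins_per_day
    return np.select([frac < 0.4, frac < 0.8], ["morning", "afternoon"], "evening")


def generate_observations(profiles: pd.DataFrame, effects: pd.DataFrame,
                          truth: GeneratorTruth, days: int = 3,
                          bins_per_day: int = 90, seed: int = 0) -> pd.DataFrame:
    """Simulate 5-minute epochs for every participant.

    Returns a DataFrame with the canonical observation schema plus internal
    truth columns ``_y1_std``, ``_y2_std``, ``_theta`` (standardized outcomes
    and latent score before missingness/outlier corruption).
    """
    if days > 3:
        raise ValueError("the study design observes at most 3 days")
    if bins_per_day < 12:
        raise ValueError("need at least 12 bins per day (one hour)")
    missing = set(profiles["participant_id"]) - set(effects["participant_id"])
    if missing:
        raise ValueError(f"effects table missing participants: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    eff = effects.set_index("participant_id")
    prof = profiles.set_index("participant_id")

    rows_pid, rows_day, rows_bin, rows_dow = [], [], [], []
    for pid in profiles["participant_id"]:
        n_days = min(days, int(prof.at[pid, "n_days"]) if "n_days" in prof.columns else days)
        start = int(prof.at[pid, "start_dow"]) if "start_dow" in prof.columns else 0
        for d in range(1, n_days + 1):
            rows_pid.extend([pid] * bins_per_day)
            rows_day.extend([d] * bins_per_day)
            rows_bin.extend(range(bins_per_day))
            rows_dow.extend([WEEKDAYS[(start + d - 1) % 5]] * bins_per_day)

    n = len(rows_pid)
    obs = pd.DataFrame(
        {
            "participant_id": rows_pid,
            "day_index": rows_day,
            "bin_index": rows_bin,
            "day_of_week": rows_dow,
        }
    )
    obs["time_of_day"] = _time_of_day(obs["bin_index"].to_numpy(), bins_per_day)

    scale = _truncnorm_scale_for_sd(truth.sound_sd, truth.sound_mean,
                                    truth.sound_lo, truth.sound_hi)
    sound = _truncated_normal(rng, truth.sound_mean, scale,
                              truth.sound_lo, truth.sound_hi, n)
    activity = rng.lognormal(truth.activity_logmean, truth.activity_logsd, n)

    h_low = np.minimum(sound, truth.knot)
    h_high = np.maximum(sound - truth.knot, 0.0)

    def z(v):
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    h_low_z, h_high_z, act_z = z(h_low), z(h_high), z(activity)

    g0 = eff["gamma0"].reindex(obs["participant_id"]).to_numpy()
    g_low = eff["gamma_sound_low"].reindex(obs["participant_id"]).to_numpy()
    g_high = eff["gamma_sound_high"].reindex(obs["participant_id"]).to_numpy()
    g_act = eff["gamma_act"].reindex(obs["participant_id"]).to_numpy()

    theta = (
        truth.beta0
        + g0
        + (truth.beta_sound_low + g_low) * h_low_z
        + (truth.beta_sound_high + g_high) * h_high_z
        + (truth.beta_activity + g_act) * act_z
    )
    tod = obs["time_of_day"].to_numpy()
    theta += np.select([tod == "afternoon", tod == "evening"],
                       [truth.beta_time[0], truth.beta_time[1]], 0.0)
    dow = obs["day_of_week"].to_numpy()
    for w, b in zip(WEEKDAYS[1:], truth.beta_dow):
        theta += np.where(dow == w, b, 0.0)
    ag = prof["age_group"].reindex(obs["participant_id"]).to_numpy()
    for lev, b in zip(["age_30_40", "age_40_50", "age_50_60", "age_above_60"],
                      truth.beta_age):
        theta += np.where(ag == lev, b, 0.0)
    bg = prof["bmi_group"].reindex(obs["participant_id"]).to_numpy()
    for lev, b in zip(["bmi_25_30", "bmi_30_35", "bmi_above_35"], truth.beta_bmi):
        theta += np.where(bg == lev, b, 0.0)
    gender = prof["gender"].reindex(obs["participant_id"]).to_numpy()
    theta += np.where(gender == "female", truth.beta_gender, 0.0)

    y1 = truth.lambda1 * theta + (rng.normal(0.0, truth.sigma1, n) if truth.sigma1 > 0 else 0.0)
    y2 = truth.lambda2 * theta + (rng.normal(0.0, truth.sigma2, n) if truth.sigma2 > 0 else 0.0)

    sdnn = np.maximum(truth.sdnn_mean_ms + truth.sdnn_sd_ms * y1, 1.0)
    nhf = 1.0 / (1.0 + np.exp(-truth.nhf_scale * y2))

    # 5x multiplicative outliers guarantee exceedance of the 99.5th percentile
    if truth.outlier_rate > 0:
        for arr in (sdnn, nhf):
            mask = rng.random(n) < truth.outlier_rate
            arr[mask] *= 5.0
    if truth.missing_rate > 0:
        for name, arr in (("sound", sound), ("act", activity),
                          ("sdnn", sdnn), ("nhf", nhf)):
            arr[rng.random(n) < truth.missing_rate] = np.nan

    obs["sound_dba"] = sound
    obs["activity_g"] = activity
    obs["sdnn_ms"] = sdnn
    obs["nhf"] = nhf
    obs["_theta"] = theta
    obs["_y1_std"] = y1
    obs["_y2_std"] = y2
    return obs[OBSERVATION_COLUMNS + ["_theta", "_y1_std", "_y2_std"]]


def generate_cohort(n_participants: int, truth: GeneratorTruth | None = None,
                    days: int = 3, bins_per_day: int = 90, seed: int = 0):
    """Convenience wrapper: profiles, random effects and observations.

    Sub-seeds for the three stages are derived deterministically from
    ``seed`` so cohorts are reproducible end to end.
    """
    truth = truth if truth is not None else GeneratorTruth()
    ss = np.random.SeedSequence(seed).generate_state(3)
    profiles = generate_participants(n_participants, truth, int(ss[0]) % (2**31))
    effects = generate_random_effects(profiles, truth, int(ss[1]) % (2**31))
    obs = generate_observations(profiles, effects, truth, days=days,
                                bins_per_day=bins_per_day, seed=int(ss[2]) % (2**31))
    return profiles, effects, obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs[OBSERVATION_COLUMNS].to_csv(path, index=False)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)
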