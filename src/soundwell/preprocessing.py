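"""Cleaning, filtering and standardization of 5-minute wearable epochs.

The pipeline order is fixed: aggregate -> complete-outcome filter ->
99.5th-percentile outcome-outlier filter -> short-participant exclusion ->
input imputation -> person-level discretization -> day-based train/holdout
split -> standardization.  Every stage logs its input and output row counts.

Standardization parameters (hinge sound terms, activity, outcomes) are fit
on the training rows only and applied to both splits; imputation means are
likewise computed on training days (day 1-2) only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import AGE_LEVELS, BMI_LEVELS, age_group, bmi_group

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationParams",
    "DesignMatrix",
    "aggregate_5min",
    "filter_complete_outcomes",
    "filter_outcome_outliers",
    "exclude_short_participants",
    "impute_inputs",
    "discretize_person",
    "split_train_holdout",
    "standardize",
    "run_preprocessing",
    "FIXED_EFFECT_COLUMNS",
]

OUTCOMES = ["sdnn_ms", "nhf"]
INPUTS = ["sound_dba", "activity_g"]

TOD_DUMMIES = ["tod_afternoon", "tod_evening"]  # baseline morning
DOW_DUMMIES = ["dow_Tue", "dow_Wed", "dow_Thu", "dow_Fri"]  # baseline Monday
AGE_DUMMIES = AGE_LEVELS[1:]  # baseline below 30
BMI_DUMMIES = BMI_LEVELS[1:]  # baseline below 25

#: fixed-effect design columns of the latent model, in reporting order
FIXED_EFFECT_COLUMNS = (
    ["sound_low", "sound_high", "activity"]
    + TOD_DUMMIES
    + DOW_DUMMIES
    + AGE_DUMMIES
    + BMI_DUMMIES
    + ["gender_female"]
)

#: person-level columns carried on the design for heterogeneity/moderators
PERSON_COLUMNS = [
    "neuroticism", "noise_sensitivity", "high_bp", "anxiety", "sleep_problems",
    "cui_work", "managerial", "meeting_intensive", "technical",
    "avg_sound_exposure",
]


@dataclass
class StandardizationParams:
    """Training-set means and SDs used to scale inputs and outcomes."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    knot: float = 50.0

    def transform(self, name: str, values):
        return (np.asarray(values, float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, values):
        return np.asarray(values, float) * self.sds[name] + self.means[name]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StandardizationParams":
        return cls(**json.loads(text))


@dataclass
class DesignMatrix:
    """Model-ready, row-aligned design for one data split.

    ``frame`` holds standardized outcomes ``y1`` (SDNN) and ``y2``
    (normalized-HF), standardized hinge sound terms and activity, the plain
    standardized sound level (for the pilot models), dummy covariates,
    person-level moderator columns, raw ``sound_dba`` (for subsetting at the
    knot and sound-range tables), and participant bookkeeping.
    """

    frame: pd.DataFrame
    params: StandardizationParams
    participants: list  # category order backing participant_idx codes

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def fixed_matrix(self, columns=None, const: bool = True) -> np.ndarray:
        cols = list(columns) if columns is not None else list(FIXED_EFFECT_COLUMNS)
        X = self.frame[cols].to_numpy(float)
        if const:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def outcomes(self) -> np.ndarray:
        return self.frame[["y1", "y2"]].to_numpy(float)


def _log_stage(name: str, n_in: int, n_out: int, log: list | None):
    logger.info("%s: %d -> %d rows", name, n_in, n_out)
    if log is not None:
        log.append({"stage": name, "rows_in": int(n_in), "rows_out": int(n_out)})


def aggregate_5min(records: pd.DataFrame, minute_col: str = "minute") -> pd.DataFrame:
    """Aggregate finer-grain records to 5-minute bins by within-bin means.

    Each numeric channel is averaged over its available (non-missing) values;
    a bin with no data for a channel keeps that channel missing.  Rows must
    carry ``participant_id`` and ``day_index``; ``minute_col`` gives the
    minute within day.  Already-binned input (``bin_index`` present and no
    minute column) is returned unchanged.
    """
    if len(records) == 0:
        return records.copy()
    df = records.copy()
    if minute_col not in df.columns:
        if "bin_index" in df.columns:
            return df
        raise ValueError(f"records need a {minute_col!r} or 'bin_index' column")
    df["bin_index"] = (df[minute_col] // 5).astype(int)
    keys = ["participant_id", "day_index", "bin_index"]
    numeric = [c for c in df.columns
               if c not in keys + [minute_col] and pd.api.types.is_numeric_dtype(df[c])]
    categorical = [c for c in df.columns if c not in keys + [minute_col] + numeric]
    agg = {c: "mean" for c in numeric} | {c: "first" for c in categorical}
    out = df.sort_values(keys).groupby(keys, as_index=False, sort=True).agg(agg)
    return out


def filter_complete_outcomes(records: pd.DataFrame, log: list | None = None) -> pd.DataFrame:
    """Keep only epochs where both SDNN and normalized-HF are present."""
    out = records.dropna(subset=OUTCOMES)
    _log_stage("complete_outcomes", len(records), len(out), log)
    return out


def filter_outcome_outliers(records: pd.DataFrame, percentile: float = 99.5,
                            min_records: int = 200,
                            log: list | None = None) -> pd.DataFrame:
    """Drop epochs with either outcome strictly above its 99.5th percentile.

    With fewer than ``min_records`` rows the percentile is not meaningful;
    the filter warns and passes the table through.
    """
    if len(records) < min_records:
        warnings.warn(
            f"outlier filter skipped: {len(records)} < {min_records} records",
            stacklevel=2,
        )
        _log_stage("outcome_outliers(skipped)", len(records), len(records), log)
        return records.copy()
    keep = np.ones(len(records), dtype=bool)
    for col in OUTCOMES:
        cut = np.nanpercentile(records[col].to_numpy(float), percentile)
        keep &= ~(records[col].to_numpy(float) > cut)
    out = records.loc[keep]
    _log_stage("outcome_outliers", len(records), len(out), log)
    return out


def exclude_short_participants(records: pd.DataFrame, min_records: int = 12,
                               log: list | None = None) -> pd.DataFrame:
    """Remove participants with under one hour (12 five-minute epochs) of data."""
    if len(records) == 0:
        _log_stage("short_participants", 0, 0, log)
        return records.copy()
    counts = records.groupby("participant_id")["participant_id"].transform("size")
    out = records.loc[counts >= min_records]
    _log_stage("short_participants", len(records), len(out), log)
    return out


def impute_inputs(records: pd.DataFrame, log: list | None = None) -> pd.DataFrame:
    """Mean-impute missing input cells (sound, activity); outcomes untouched.

    Imputation means come from training days (day_index <= 2) so the holdout
    never leaks into them.
    """
    out = records.copy()
    train = out[out["day_index"] <= 2] if "day_index" in out.columns else out
    if len(train) == 0:
        train = out
    for col in INPUTS:
        if col in out.columns:
            out[col] = out[col].fillna(train[col].mean())
    _log_stage("impute_inputs", len(records), len(out), log)
    return out


def discretize_person(profiles: pd.DataFrame) -> pd.DataFrame:
    """Attach age_group (5 levels) and bmi_group (4 levels) to profiles."""
    out = profiles.copy()
    out["age_group"] = age_group(out["age_years"])
    out["bmi_group"] = bmi_group(out["bmi"])
    return out


def split_train_holdout(records: pd.DataFrame, log: list | None = None):
    """Days 1-2 of every participant train the models; day 3 is held out."""
    train = records.loc[records["day_index"] <= 2]
    holdout = records.loc[records["day_index"] == 3]
    _log_stage("split_train", len(records), len(train), log)
    _log_stage("split_holdout", len(records), len(holdout), log)
    return train, holdout


def _build_frame(records: pd.DataFrame, profiles: pd.DataFrame,
                 params: StandardizationParams, participants: list) -> pd.DataFrame:
    df = records.merge(
        profiles[["participant_id", "age_group", "bmi_group", "gender"] + PERSON_COLUMNS],
        on="participant_id", how="left", validate="many_to_one",
    )
    sound = df["sound_dba"].to_numpy(float)
    h_low = np.minimum(sound, params.knot)
    h_high = np.maximum(sound - params.knot, 0.0)
    out = pd.DataFrame(index=df.index)
    out["participant_id"] = df["participant_id"].to_numpy()
    out["day_index"] = df["day_index"].to_numpy()
    out["sound_dba"] = sound
    out["y1"] = params.transform("sdnn", df["sdnn_ms"])
    out["y2"] = params.transform("nhf", df["nhf"])
    out["sound_low"] = params.transform("sound_low", h_low)
    out["sound_high"] = params.transform("sound_high", h_high)
    out["sound_lin"] = params.transform("sound", sound)
    out["sound_lin_sq"] = out["sound_lin"] ** 2
    out["activity"] = params.transform("activity", df["activity_g"])
    out["tod_afternoon"] = (df["time_of_day"] == "afternoon").astype(float)
    out["tod_evening"] = (df["time_of_day"] == "evening").astype(float)
    for w in ["Tue", "Wed", "Thu", "Fri"]:
        out[f"dow_{w}"] = (df["day_of_week"] == w).astype(float)
    for lev in AGE_DUMMIES:
        out[lev] = (df["age_group"] == lev).astype(float)
    for lev in BMI_DUMMIES:
        out[lev] = (df["bmi_group"] == lev).astype(float)
    out["gender_female"] = (df["gender"] == "female").astype(float)
    for col in PERSON_COLUMNS:
        out[col] = df[col].astype(float).to_numpy()
    cat = pd.Categorical(out["participant_id"], categories=participants)
    out["participant_idx"] = cat.codes
    if (out["participant_idx"] < 0).any():
        raise ValueError("records contain participants absent from the training split")
    return out


def standardize(train: pd.DataFrame, holdout: pd.DataFrame,
                profiles: pd.DataFrame, knot: float = 50.0):
    """Fit scaling on the training split, apply to both splits.

    Hinge sound terms are computed on the raw dBA scale at the knot before
    scaling.  Returns ``(train_design, holdout_design, params)``; the holdout
    design is ``None`` when the holdout is empty.
    """
    if len(train) == 0:
        raise ValueError("training split is empty")
    params = StandardizationParams(knot=knot)
    sound = train["sound_dba"].to_numpy(float)
    raw = {
        "sound_low": np.minimum(sound, knot),
        "sound_high": np.maximum(sound - knot, 0.0),
        "sound": sound,
        "activity": train["activity_g"].to_numpy(float),
        "sdnn": train["sdnn_ms"].to_numpy(float),
        "nhf": train["nhf"].to_numpy(float),
    }
    for name, vals in raw.items():
        params.means[name] = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1))
        if sd <= 0:
            raise ValueError(f"zero variance in {name}; cannot standardize")
        params.sds[name] = sd

    participants = sorted(train["participant_id"].unique())
    train_design = DesignMatrix(_build_frame(train, profiles, params, participants),
                                params, participants)
    holdout_design = None
    if len(holdout):
        mask = holdout["participant_id"].isin(participants)
        holdout_design = DesignMatrix(
            _build_frame(holdout.loc[mask], profiles, params, participants),
            params, participants)
    return train_design, holdout_design, params


def run_preprocessing(observations: pd.DataFrame, profiles: pd.DataFrame,
                      knot: float = 50.0, min_records: int = 12):
    """Full pipeline from raw epochs to standardized design matrices.

    Returns ``(train_design, holdout_design, params, stage_log)``.
    """
    log: list = []
    obs = aggregate_5min(observations)
    _log_stage("aggregate_5min", len(observations), len(obs), log)
    obs = filter_complete_outcomes(obs, log)
    obs = filter_outcome_outliers(obs, log=log)
    obs = exclude_short_participants(obs, min_records=min_records, log=log)
    obs = impute_inputs(obs, log)
    prof = discretize_person(profiles)
    train, holdout = split_train_holdout(obs, log)
    train_design, holdout_design, params = standardize(train, holdout, prof, knot=knot)
    return train_design, holdout_design, params, log
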