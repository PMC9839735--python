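"""End-to-end pipeline orchestration and report rendering.

A run executes simulate -> preprocess -> pilot -> fit -> heterogeneity ->
evaluate.  Every stage reads its inputs from, and writes its artifacts
(CSV/JSON) to, one run directory, so stages can be re-run individually; a
log records row counts, seeds and convergence status.  All randomness flows
from a single root seed, split deterministically per stage.
``render_report`` builds tables and figures strictly from stage artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, heterogeneity, pilot
from .cohort import (
    GeneratorTruth,
    generate_observations,
    generate_participants,
    generate_random_effects,
    write_observations,
)
from .latent import LatentWellbeingModel, ModelSpec
from .preprocessing import (
    DesignMatrix,
    StandardizationParams,
    discretize_person,
    run_preprocessing,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_stage", "render_report",
           "StageError", "design_from_artifacts"]

STAGES = ["simulate", "preprocess", "pilot", "fit", "heterogeneity", "evaluate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run (round-trips via YAML)."""

    n_participants: int = 40
    days: int = 3
    bins_per_day: int = 50
    truth: GeneratorTruth = field(default_factory=GeneratorTruth)
    knot: float = 50.0
    min_records: int = 12
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    het_chains: int = 2
    het_warmup: int = 300
    het_draws: int = 300
    cv_folds: int = 5
    spline_df: int = 6
    n_boot: int = 0
    seed: int = 0
    require_convergence: bool = True

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if isinstance(d.get("truth"), dict):
            t = d["truth"]
            for key in ("beta_time", "beta_dow", "beta_age", "beta_bmi"):
                if key in t:
                    t[key] = tuple(t[key])
            d["truth"] = GeneratorTruth(**t)
        return cls(**d)


def _stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {s: int(v) % (2**31) for s, v in zip(STAGES, state)}


def design_from_artifacts(outdir):
    """Rebuild the train/holdout DesignMatrix pair written by `preprocess`."""
    outdir = Path(outdir)
    params = StandardizationParams.from_json(
        (outdir / "standardization.json").read_text())
    meta = json.loads((outdir / "participants.json").read_text())
    train = DesignMatrix(pd.read_csv(outdir / "train_design.csv"), params,
                         meta["participants"])
    hpath = outdir / "holdout_design.csv"
    holdout = None
    if hpath.exists():
        holdout = DesignMatrix(pd.read_csv(hpath), params, meta["participants"])
    return train, holdout, params


# --------------------------------------------------------------------- #
# stages (each reads artifacts from outdir and writes its own)

def _stage_simulate(cfg: PipelineConfig, outdir: Path, seeds: dict):
    profiles = generate_participants(cfg.n_participants, cfg.truth, seeds["simulate"])
    effects = generate_random_effects(profiles, cfg.truth, seeds["simulate"] + 1)
    obs = generate_observations(profiles, effects, cfg.truth, days=cfg.days,
                                bins_per_day=cfg.bins_per_day,
                                seed=seeds["simulate"] + 2)
    profiles.to_csv(outdir / "profiles.csv", index=False)
    effects.to_csv(outdir / "random_effects_truth.csv", index=False)
    write_observations(obs, outdir / "observations.csv")
    (outdir / "truth.json").write_text(cfg.truth.to_json())


def _stage_preprocess(cfg: PipelineConfig, outdir: Path, seeds: dict):
    obs = pd.read_csv(outdir / "observations.csv")
    profiles = pd.read_csv(outdir / "profiles.csv")
    train, holdout, params, log = run_preprocessing(
        obs, profiles, knot=cfg.knot, min_records=cfg.min_records)
    train.frame.to_csv(outdir / "train_design.csv", index=False)
    if holdout is not None:
        holdout.frame.to_csv(outdir / "holdout_design.csv", index=False)
    (outdir / "standardization.json").write_text(params.to_json())
    (outdir / "participants.json").write_text(
        json.dumps({"participants": list(train.participants)}))
    (outdir / "preprocess_log.json").write_text(json.dumps(log, indent=2))


def _stage_pilot(cfg: PipelineConfig, outdir: Path, seeds: dict):
    train, _, _ = design_from_artifacts(outdir)
    out = {}
    for outcome in ("sdnn", "nhf"):
        lin = pilot.fit_curvilinear_mixed(train, outcome, quadratic=False)
        quad = pilot.fit_curvilinear_mixed(train, outcome, quadratic=True)
        pref, delta = pilot.compare_aic(quad, lin)
        out[outcome] = {
            "aic_linear": lin.aic,
            "aic_quadratic": quad.aic,
            "delta_aic_quad_minus_lin": delta,
            "preferred": "quadratic" if pref is quad else "linear",
            "coef_quadratic": {k: float(v) for k, v in quad.params.items()},
            "re_structure": quad.re_structure,
        }
    est = pilot.estimate_optimal_sound(train, spline_df=cfg.spline_df,
                                       n_boot=cfg.n_boot, seed=seeds["pilot"])
    out["optimal_sound"] = {
        "optimum_dba": est.optimum_dba,
        "interval": est.interval,
        "flat_or_monotone": est.flat_or_monotone,
        "grid": est.grid.tolist(),
        "curve": est.curve.tolist(),
    }
    (outdir / "pilot.json").write_text(json.dumps(out, indent=2))


def _stage_fit(cfg: PipelineConfig, outdir: Path, seeds: dict):
    train, holdout, params = design_from_artifacts(outdir)
    model = LatentWellbeingModel.from_design(train, ModelSpec())
    res = model.fit(draws=cfg.draws, warmup=cfg.warmup, chains=cfg.chains,
                    seed=seeds["fit"])
    report = res.check_convergence()
    res.summary().to_csv(outdir / "posterior_summary.csv")
    res.random_effect_table().to_csv(outdir / "random_effects_posterior.csv",
                                     index=False)
    beta_mean = {n: res.coef(n) for n in res.model.fixed_names}
    (outdir / "fixed_effects_mean.json").write_text(json.dumps(beta_mean, indent=2))
    sound_sd = params.sds["sound"]
    translation = {seg: res.unstandardize_effect(seg, sound_sd, delta=10.0)
                   for seg in ("sound_low", "sound_high")}
    (outdir / "effect_translation.json").write_text(json.dumps(translation, indent=2))
    (outdir / "convergence.json").write_text(json.dumps({
        "passed": report.passed, "max_rhat": report.max_rhat,
        "divergences": report.divergences, "min_ess": report.min_ess}, indent=2))
    if holdout is not None:
        res.predict(holdout).to_csv(outdir / "predictions_holdout.csv", index=False)
    if cfg.require_convergence and not report.passed:
        raise RuntimeError(f"convergence check failed: {report}")


def _stage_heterogeneity(cfg: PipelineConfig, outdir: Path, seeds: dict):
    train, _, _ = design_from_artifacts(outdir)
    profiles = discretize_person(pd.read_csv(outdir / "profiles.csv"))
    out = heterogeneity.select_moderators(
        train, profiles, draws=cfg.het_draws, warmup=cfg.het_warmup,
        chains=cfg.het_chains, seed=seeds["heterogeneity"], cv_folds=cfg.cv_folds)
    tables, slope_tabs = [], []
    for subset, d in out["subsets"].items():
        t = d["selection"].to_table()
        t.columns = pd.MultiIndex.from_product([[subset], t.columns])
        tables.append(t)
        slope_tabs.append(d["slopes"])
    pd.concat(tables, axis=1).to_csv(outdir / "selection_table.csv")
    pd.concat(slope_tabs, ignore_index=True).to_csv(outdir / "slopes.csv", index=False)
    (outdir / "selection.json").write_text(json.dumps({
        "consensus_union": out["consensus_union"],
        "per_subset": {s: d["selection"].consensus
                       for s, d in out["subsets"].items()}}, indent=2))


def _stage_evaluate(cfg: PipelineConfig, outdir: Path, seeds: dict):
    train, holdout, _ = design_from_artifacts(outdir)
    if holdout is None:
        raise RuntimeError("no holdout split; evaluation impossible")
    consensus = json.loads((outdir / "selection.json").read_text())["consensus_union"]
    metrics = evaluation.compare_moderator_sets(
        train, holdout, consensus, heterogeneity.PERSON_PREDICTORS,
        draws=cfg.draws, warmup=cfg.warmup, chains=cfg.chains,
        seed=seeds["evaluate"])
    metrics.to_csv(outdir / "metrics.csv", index=False)
    beta_mean = json.loads((outdir / "fixed_effects_mean.json").read_text())
    strata = {"high_bp": "high_bp",
              "normal_bp": train.frame["high_bp"] == 0,
              "cui_work": "cui_work",
              "regular_computer_use": train.frame["cui_work"] == 0}
    emm = evaluation.emm_group_table(train, beta_mean, strata)
    emm.to_csv(outdir / "emm.csv")
    if consensus:
        _, curves = heterogeneity.moderator_refit(
            train, consensus, draws=cfg.het_draws, warmup=cfg.het_warmup,
            chains=cfg.het_chains, seed=seeds["evaluate"] + 1)
        curves.to_csv(outdir / "moderator_curves.csv", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "pilot": _stage_pilot,
    "fit": _stage_fit,
    "heterogeneity": _stage_heterogeneity,
    "evaluate": _stage_evaluate,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir) -> None:
    """Run one named stage against an existing run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    try:
        _STAGE_FNS[stage](cfg, outdir, seeds)
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    except BaseException as e:
        raise StageError(stage, e) from e


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage failure raises :class:`StageError` tagged with the stage name;
    the partial status is recorded in ``run_status.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    seeds = _stage_seeds(config.seed)
    status = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    for stage in STAGES:
        try:
            _STAGE_FNS[stage](config, outdir, seeds)
            status["stages"][stage] = "ok"
            logger.info("stage %s ok", stage)
        except BaseException as e:
            status["stages"][stage] = f"failed: {e}"
            (outdir / "run_status.json").write_text(json.dumps(status, indent=2))
            raise StageError(stage, e) from e
    (outdir / "run_status.json").write_text(json.dumps(status, indent=2))
    return outdir


def render_report(outdir) -> Path:
    """Render a markdown report with figures from stage artifacts only.

    Sections whose artifacts are missing are marked absent.  Nothing is
    recomputed; with no artifacts at all, rendering fails.
    """
    outdir = Path(outdir)
    artifacts = {p.name for p in outdir.iterdir()} if outdir.exists() else set()
    needed = {"pilot.json", "posterior_summary.csv", "selection_table.csv",
              "metrics.csv", "emm.csv", "slopes.csv"}
    if not (artifacts & needed):
        raise FileNotFoundError("no stage artifacts found; run the pipeline first")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = ["# Sound-wellbeing analysis report", ""]

    if "pilot.json" in artifacts:
        pj = json.loads((outdir / "pilot.json").read_text())
        opt = pj["optimal_sound"]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(opt["grid"], opt["curve"])
        ax.axvline(opt["optimum_dba"], ls="--", color="grey")
        ax.set_xlabel("sound level (dBA)")
        ax.set_ylabel("stacked standardized outcome (smooth)")
        fig.savefig(outdir / "fig_sound_smooth.svg")
        plt.close(fig)
        lines += ["## Pilot: sound smooth",
                  f"Optimum at {opt['optimum_dba']:.1f} dBA "
                  f"(flat/monotone flag: {opt['flat_or_monotone']}).",
                  "![smooth](fig_sound_smooth.svg)", ""]
    else:
        lines += ["## Pilot: sound smooth", "_artifact absent_", ""]

    if "posterior_summary.csv" in artifacts:
        summ = pd.read_csv(outdir / "posterior_summary.csv")
        lines += ["## Fixed effects (posterior mean, 90% CrI)",
                  summ.to_markdown(index=False), ""]
    else:
        lines += ["## Fixed effects", "_artifact absent_", ""]

    if "slopes.csv" in artifacts:
        slopes = pd.read_csv(outdir / "slopes.csv")
        for subset, g in slopes.groupby("subset"):
            g = g.sort_values("slope_mean").reset_index(drop=True)
            # 60% credible interval of a normal posterior approximation
            half = 0.8416 * g["slope_sd"]
            fig, ax = plt.subplots(figsize=(5, max(3, len(g) * 0.06)))
            ax.hlines(range(len(g)), g["slope_mean"] - half, g["slope_mean"] + half,
                      color="tab:blue", lw=1)
            ax.plot(g["slope_mean"], range(len(g)), ".", color="black", ms=2)
            ax.axvline(g["slope_mean"].mean(), ls="--", color="grey")
            ax.set_xlabel(f"sound slope ({subset})")
            ax.set_ylabel("participant (sorted)")
            fig.savefig(outdir / f"fig_caterpillar_{subset}.svg")
            plt.close(fig)
            lines += [f"![caterpillar {subset}](fig_caterpillar_{subset}.svg)"]
        lines += [""]
    else:
        lines += ["## Random sound slopes", "_artifact absent_", ""]

    if "selection_table.csv" in artifacts:
        sel = pd.read_csv(outdir / "selection_table.csv")
        lines += ["## Heterogeneity selection", sel.to_markdown(index=False), ""]
    else:
        lines += ["## Heterogeneity selection", "_artifact absent_", ""]

    if "moderator_curves.csv" in artifacts:
        curves = pd.read_csv(outdir / "moderator_curves.csv")
        mods = [m for m in curves["moderator"].unique() if m != "(none)"]
        if mods:
            fig, axes = plt.subplots(1, len(mods), figsize=(5 * len(mods), 4),
                                     squeeze=False)
            for ax, mod in zip(axes[0], mods):
                for level, g in curves[curves["moderator"] == mod].groupby("level"):
                    ax.plot(g["sound_dba"], g["wellbeing"],
                            label=f"{mod}={int(level)}")
                ax.set_xlabel("sound level (dBA)")
                ax.set_ylabel("latent wellbeing (std)")
                ax.legend()
            fig.savefig(outdir / "fig_moderators.svg")
            plt.close(fig)
            lines += ["![moderators](fig_moderators.svg)", ""]

    for name, title in (("metrics.csv", "Holdout metrics"),
                        ("emm.csv", "Adjusted wellbeing by sound range")):
        if name in artifacts:
            lines += [f"## {title}",
                      pd.read_csv(outdir / name).to_markdown(index=False), ""]
        else:
            lines += [f"## {title}", "_artifact absent_", ""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
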