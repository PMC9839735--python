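"""Two-step heterogeneity method: subset fits, slope extraction, penalized
selection, consensus, and moderator refits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

import soundwell as sw
from soundwell.heterogeneity import (
    RegularizedFit,
    consensus_select,
    extract_slopes,
    fit_regularized,
    fit_subset_random_model,
    moderator_refit,
    person_design,
)
from soundwell.preprocessing import discretize_person


@pytest.fixture(scope="module")
def het_cohort():
    """Cohort with strong planted moderation of the sound slopes."""
    truth = sw.GeneratorTruth(het_coeffs={"high_bp": -0.10, "cui_work": 0.12},
                              sigma_r=0.04)
    profiles, effects, obs = sw.generate_cohort(120, truth, days=3,
                                                bins_per_day=90, seed=42)
    train, holdout, params, _ = sw.run_preprocessing(obs, profiles)
    return discretize_person(profiles), effects, train, truth


@pytest.fixture(scope="module")
def oracle_slopes(het_cohort):
    """Generator-truth slope table (no model fitting involved)."""
    profiles, effects, *_ = het_cohort
    return pd.DataFrame({
        "participant_id": effects["participant_id"],
        "slope_mean": effects["gamma_sound_low"],
        "slope_sd": 0.0,
        "subset": "below_50",
    })


class TestSubsetFits:
    def test_mu_recovery_and_slope_correlation(self, het_cohort):
        profiles, effects, train, truth = het_cohort
        res = fit_subset_random_model(train, "below_50", draws=300, warmup=300,
                                      chains=2, seed=3)
        assert res.check_convergence().divergences == 0
        s = res.summary()
        # the sound-slope mean is the analogue of the fixed effect; planted
        # moderation shifts the population mean by the moderator prevalences
        expected = (truth.beta_sound_low
                    - 0.10 * profiles["high_bp"].mean()
                    + 0.12 * profiles["cui_work"].mean())
        assert abs(s.loc["mu_gamma[sound_low]", "mean"] - expected) <= 0.03
        slopes = extract_slopes(res, "below_50", design=train)
        truth_slopes = (truth.beta_sound_low + effects.set_index(
            "participant_id")["gamma_sound_low"]).reindex(slopes["participant_id"])
        r = np.corrcoef(slopes["slope_mean"], truth_slopes)[0, 1]
        assert r > 0.7

    def test_homogeneous_truth_slopes_concentrate(self):
        truth = sw.GeneratorTruth(sigma_r=0.0, het_coeffs={})
        profiles, _, obs = sw.generate_cohort(40, truth, days=2,
                                              bins_per_day=40, seed=8)
        train, _, _, _ = sw.run_preprocessing(obs, profiles)
        res = fit_subset_random_model(train, "below_50", draws=300, warmup=300,
                                      chains=2, seed=9)
        slopes = extract_slopes(res, "below_50", design=train)
        assert slopes["slope_mean"].std(ddof=1) < 0.02

    def test_too_few_participants_refused(self, designs):
        train, *_ = designs
        with pytest.raises(ValueError, match="refused"):
            fit_subset_random_model(train, "below_50", min_participants=1000)

    def test_empty_subset_refused(self, designs):
        train, *_ = designs
        below_only = sw.DesignMatrix(
            train.frame.loc[train.frame["sound_dba"] < 50].copy(),
            train.params, train.participants)
        with pytest.raises(ValueError):
            fit_subset_random_model(below_only, "above_50")

    def test_invalid_subset_name(self, designs):
        train, *_ = designs
        with pytest.raises(ValueError):
            fit_subset_random_model(train, "mid_50")

    def test_subset_independence(self, het_cohort):
        """Permuting above-knot rows leaves the below-knot fit bit-identical."""
        profiles, _, train, _ = het_cohort
        above = train.frame["sound_dba"] >= 50
        shuffled = train.frame.loc[above].sample(frac=1, random_state=0)
        perm = pd.concat([train.frame.loc[~above], shuffled])
        train_perm = sw.DesignMatrix(perm, train.params, train.participants)
        a = fit_subset_random_model(train, "below_50", draws=60, warmup=60,
                                    chains=1, seed=5)
        b = fit_subset_random_model(train_perm, "below_50", draws=60, warmup=60,
                                    chains=1, seed=5)
        np.testing.assert_array_equal(a.posterior["mu_gamma"], b.posterior["mu_gamma"])


class TestRegularized:
    def test_zero_penalty_equals_ols(self, oracle_slopes, het_cohort):
        profiles = het_cohort[0]
        for method in ("lasso", "elasticnet", "adaptive_lasso"):
            fit = fit_regularized(oracle_slopes, profiles, method, grid=[0.0])
            X = person_design(profiles).loc[oracle_slopes["participant_id"]]
            ols = LinearRegression().fit(X.to_numpy(), oracle_slopes["slope_mean"])
            np.testing.assert_allclose(fit.coef.to_numpy(), ols.coef_, atol=1e-6)

    def test_infinite_penalty_shrinks_everything(self, oracle_slopes, het_cohort):
        fit = fit_regularized(oracle_slopes, het_cohort[0], "lasso", grid=[1e9])
        assert (fit.coef.abs() < 1e-12).all()

    def test_unknown_method(self, oracle_slopes, het_cohort):
        with pytest.raises(ValueError):
            fit_regularized(oracle_slopes, het_cohort[0], "ridge")

    def test_selection_consistency_on_oracle_slopes(self):
        """Small planted effects are exactly selectable when the slope table
        is observed without estimation noise (only sigma_r)."""
        truth = sw.GeneratorTruth(het_coeffs={"high_bp": -0.02, "cui_work": 0.03},
                                  sigma_r=0.005)
        per_method = {m: 0 for m in ("lasso", "elasticnet", "adaptive_lasso")}
        n_seeds = 10
        for seed in range(n_seeds):
            profiles = discretize_person(
                sw.generate_participants(200, truth, seed=500 + seed))
            effects = sw.generate_random_effects(profiles, truth, seed=600 + seed)
            slopes = pd.DataFrame({
                "participant_id": effects["participant_id"],
                "slope_mean": effects["gamma_sound_low"],
                "slope_sd": 0.0, "subset": "below_50"})
            for m in per_method:
                fit = fit_regularized(slopes, profiles, m, seed=seed)
                per_method[m] += fit.support == {"high_bp", "cui_work"}
        for m, wins in per_method.items():
            assert wins >= 8, (m, wins, n_seeds)

    def test_adaptive_weight_capping(self):
        rng = np.random.default_rng(0)
        n = 60
        prof = discretize_person(pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "age_years": 40.0, "bmi": 26.0, "gender": "male",
            "neuroticism": rng.normal(size=n),
            "noise_sensitivity": rng.normal(size=n),
            "avg_sound_exposure": 50.0,
            "high_bp": False, "anxiety": False, "cui_work": False,
            "sleep_problems": False, "managerial": False,
            "meeting_intensive": False, "technical": False}))
        X = person_design(prof)
        # outcome exactly orthogonal to every predictor: OLS coefficients ~ 0
        y = np.ones(n)
        slopes = pd.DataFrame({"participant_id": prof["participant_id"],
                               "slope_mean": y, "slope_sd": 0.0,
                               "subset": "below_50"})
        fit = fit_regularized(slopes, prof, "adaptive_lasso", seed=0)
        assert len(fit.capped_weights) > 0


class TestConsensus:
    def _fit(self, method, support):
        coef = pd.Series(0.0, index=["a", "b", "c", "d"])
        coef[list(support)] = 0.5
        return RegularizedFit(method, coef, 0.0, 0.1, 1.0)

    def test_identical_supports(self):
        fits = [self._fit(m, {"a", "c"}) for m in ("lasso", "elasticnet",
                                                   "adaptive_lasso")]
        assert consensus_select(fits).consensus == ["a", "c"]

    def test_disjoint_supports_empty(self):
        fits = [self._fit("lasso", {"a"}), self._fit("elasticnet", {"b"}),
                self._fit("adaptive_lasso", {"c"})]
        assert consensus_select(fits).consensus == []

    def test_adding_method_never_grows_consensus(self):
        base = [self._fit("lasso", {"a", "b"}), self._fit("elasticnet", {"a", "b", "c"})]
        extra = base + [self._fit("adaptive_lasso", {"b", "d"})]
        small = set(consensus_select(extra).consensus)
        big = set(consensus_select(base).consensus)
        assert small <= big

    def test_consensus_subset_of_every_support(self, oracle_slopes, het_cohort):
        profiles = het_cohort[0]
        fits = [fit_regularized(oracle_slopes, profiles, m, seed=1)
                for m in ("lasso", "elasticnet", "adaptive_lasso")]
        sel = consensus_select(fits)
        for f in fits:
            assert set(sel.consensus) <= f.support
        table = sel.to_table()
        assert set(table.columns) == {"lasso", "elasticnet", "adaptive_lasso"}


class TestModeratorRefit:
    def test_no_moderators_equals_base_fit(self, designs):
        train, *_ = designs
        res_mod, _ = moderator_refit(train, [], draws=60, warmup=60, chains=1, seed=2)
        base = sw.LatentWellbeingModel.from_design(train).fit(
            draws=60, warmup=60, chains=1, seed=2)
        np.testing.assert_array_equal(res_mod.posterior["beta"],
                                      base.posterior["beta"])

    def test_planted_moderation_bends_group_curve(self, het_cohort):
        profiles, _, train, _ = het_cohort
        res, curves = moderator_refit(train, ["high_bp", "cui_work"],
                                      draws=250, warmup=250, chains=2, seed=4)
        # interaction coefficients recover the planted signs
        assert res.coef("high_bp:sound_low") < 0
        assert res.coef("cui_work:sound_low") > 0
        hbp = curves[curves["moderator"] == "high_bp"]
        diff = (hbp[hbp["level"] == 1].set_index("sound_dba")["wellbeing"]
                - hbp[hbp["level"] == 0].set_index("sound_dba")["wellbeing"])
        # negative slope moderation: the high-BP curve falls away with rising
        # sound relative to the normal-BP curve
        assert (np.diff(diff.to_numpy()) < 1e-9).all()
        assert diff.iloc[-1] < diff.iloc[0]
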