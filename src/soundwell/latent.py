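"""Hierarchical Bayesian latent physiological-wellbeing model.

Two standardized HRV outcomes (SDNN, normalized-HF) are driven by one latent
wellbeing score through factor loadings:

    y_h = lambda_h * eta + e_h,        e_h ~ N(0, sigma_h^2)
    eta = X beta + sum_m z_m * gamma_mj,  gamma_mj ~ N(mu_m, sigma_gm^2)

with participant-level random effects gamma (intercept, hinge sound slopes,
activity slope).  The SDNN loading is fixed at lambda_1 = 1 to anchor the
scale and sign of the latent variable (higher HRV = higher wellbeing);
lambda_2 is estimated freely.  In the population model the random-effect
means mu_m are fixed at zero and fixed effects carry the population
structure; in ``random_means`` mode (used for the heterogeneity step-1 fits)
there are no fixed effects and the mu_m are estimated.

Error SDs get half-Cauchy priors; every other parameter a diffuse normal.
Sampling is Hamiltonian Monte Carlo with a non-centered parameterization of
the random effects, four chains by default, validated by split-R-hat < 1.1
and a zero-divergence check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from . import hmc
from .preprocessing import FIXED_EFFECT_COLUMNS, DesignMatrix, StandardizationParams

__all__ = [
    "ModelSpec",
    "LatentWellbeingModel",
    "LatentWellbeingResults",
    "ConvergenceReport",
    "unstandardize_effect",
    "summarize_posterior",
]


@dataclass
class ModelSpec:
    """Term lists and prior settings for the latent model."""

    fixed_effects: list = field(default_factory=lambda: list(FIXED_EFFECT_COLUMNS))
    random_effects: list = field(
        default_factory=lambda: ["const", "sound_low", "sound_high", "activity"]
    )
    moderators: list = field(default_factory=list)
    prior_sd_normal: float = 5.0
    prior_scale_cauchy: float = 2.5
    random_means: bool = False  # estimate non-zero random-effect means (no fixed effects)


def unstandardize_effect(coef_std, sound_sd: float, delta: float = 10.0):
    """Percent change in latent wellbeing per ``delta`` dBA.

    With standardized input and outcomes, a coefficient is the SD change in
    wellbeing per SD of sound; rescaling by ``delta / sound_sd`` and
    multiplying by 100 gives percent-of-SD change per ``delta`` dBA.
    Elementwise over arrays of posterior draws.
    """
    if sound_sd <= 0:
        raise ValueError("sound_sd must be positive")
    return 100.0 * (delta / sound_sd) * np.asarray(coef_std)


def _term_column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a fixed-effect term name (plain column or 'mod:segment')."""
    if name == "const":
        return np.ones(len(df))
    if ":" in name:
        mod, seg = name.split(":", 1)
        return df[mod].to_numpy(float) * df[seg].to_numpy(float)
    return df[name].to_numpy(float)


def _fixed_design(df: pd.DataFrame, spec: "ModelSpec", drop_constant: bool = False,
                  names: list | None = None):
    """Fixed-effects matrix for a design frame.

    When ``names`` is given (prediction on a new split), exactly those
    columns are built.  Otherwise the term list comes from the spec:
    const + fixed_effects + moderator x hinge interactions.
    """
    if spec.random_means:
        return [], np.zeros((len(df), 0)), []
    if names is None:
        names = ["const"] + list(spec.fixed_effects)
        for mod in spec.moderators:
            for seg in ("sound_low", "sound_high"):
                names.append(f"{mod}:{seg}")
    cols, kept, dropped = [], [], []
    for name in names:
        v = _term_column(df, name)
        if drop_constant and name != "const" and np.ptp(v) == 0:
            dropped.append(name)
            continue
        kept.append(name)
        cols.append(v)
    return kept, np.column_stack(cols), dropped


def _random_design(df: pd.DataFrame, spec: "ModelSpec") -> np.ndarray:
    return np.column_stack([
        np.ones(len(df)) if c == "const" else df[c].to_numpy(float)
        for c in spec.random_effects])


@dataclass
class ConvergenceReport:
    passed: bool
    max_rhat: float
    divergences: int
    min_ess: float

    def __str__(self):
        status = "PASS" if self.passed else "FAIL"
        return (f"convergence {status}: max R-hat {self.max_rhat:.4f}, "
                f"{self.divergences} divergences, min ESS {self.min_ess:.0f}")


class LatentWellbeingModel:
    """Simultaneous two-outcome latent-variable mixed model.

    Parameters
    ----------
    endog : (n, 2) array of standardized outcomes (SDNN, normalized-HF)
    exog : (n, p) fixed-effects design (may have zero columns)
    exog_re : (n, q) random-effects design
    groups : (n,) integer participant codes in 0..J-1 (-1 never allowed here)
    """

    def __init__(self, endog, exog, exog_re, groups, spec: ModelSpec,
                 fixed_names=None, random_names=None, participants=None):
        self.y = np.asarray(endog, float)
        if self.y.ndim != 2 or self.y.shape[1] != 2:
            raise ValueError("endog must be (n, 2): exactly two outcomes")
        self.X = np.asarray(exog, float).reshape(len(self.y), -1)
        self.Z = np.asarray(exog_re, float)
        self.groups = np.asarray(groups, int)
        if self.groups.min(initial=0) < 0:
            raise ValueError("groups contain an unknown participant index")
        self.spec = spec
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.J = int(self.groups.max()) + 1 if self.n else 0
        self.fixed_names = list(fixed_names) if fixed_names is not None else [
            f"x{k}" for k in range(self.p)]
        self.random_names = list(random_names) if random_names is not None else [
            f"z{m}" for m in range(self.q)]
        self.participants = list(participants) if participants is not None else list(range(self.J))

        # thin-QR whitening of the fixed-effects block: decorrelates the
        # posterior so a diagonal mass matrix is adequate
        if self.p:
            Q, R = np.linalg.qr(self.X)
            self._Xw = Q * np.sqrt(self.n)
            self._R = R / np.sqrt(self.n)
        else:
            self._Xw = np.zeros((self.n, 0))
            self._R = np.zeros((0, 0))

        p, q = self.p, self.q
        self._i_lam = p
        self._i_ls = p + 1
        self._i_lsg = p + 3
        self._i_mu = p + 3 + q
        self._i_u = self._i_mu + (q if spec.random_means else 0)
        self.dim = self._i_u + self.J * q

    # ------------------------------------------------------------------ #

    def _unpack(self, vec):
        p, q = self.p, self.q
        beta_w = vec[:p]
        lam2 = vec[self._i_lam]
        ls = vec[self._i_ls:self._i_ls + 2]
        lsg = vec[self._i_lsg:self._i_lsg + q]
        mu = vec[self._i_mu:self._i_mu + q] if self.spec.random_means else np.zeros(q)
        u = vec[self._i_u:].reshape(self.J, q)
        return beta_w, lam2, ls, lsg, mu, u

    def beta_from_white(self, beta_w):
        """Map whitened fixed-effect coefficients back to the design scale."""
        if self.p == 0:
            return beta_w
        return np.linalg.solve(self._R, np.atleast_1d(beta_w))

    def logp_grad(self, vec):
        """Unnormalized log posterior and its exact gradient."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logp, grad = self._logp_grad(vec)
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(grad)
        return logp, grad

    def _logp_grad(self, vec):
        sn2 = self.spec.prior_sd_normal**2
        sc2 = self.spec.prior_scale_cauchy**2
        beta_w, lam2, ls, lsg, mu, u = self._unpack(vec)
        # exp clipped: proposals far outside the support are rejected anyway
        sig = np.exp(np.clip(ls, -20.0, 20.0))
        sig_g = np.exp(np.clip(lsg, -20.0, 20.0))

        gamma = mu[None, :] + sig_g[None, :] * u          # (J, q)
        re_part = np.einsum("nq,nq->n", self.Z, gamma[self.groups])
        eta = (self._Xw @ beta_w if self.p else 0.0) + re_part

        lams = np.array([1.0, lam2])
        logp = 0.0
        g_eta = np.zeros(self.n)
        rss = np.empty(2)
        r2 = None
        for h in range(2):
            r = self.y[:, h] - lams[h] * eta
            rss[h] = r @ r
            logp += -self.n * ls[h] - 0.5 * rss[h] / sig[h] ** 2
            g_eta += (lams[h] / sig[h] ** 2) * r
            if h == 1:
                r2 = r

        grad = np.zeros_like(vec)
        if self.p:
            grad[: self.p] = self._Xw.T @ g_eta - beta_w / sn2
            logp += -0.5 * (beta_w @ beta_w) / sn2
        grad[self._i_lam] = (r2 @ eta) / sig[1] ** 2 - lam2 / sn2
        logp += -0.5 * lam2**2 / sn2
        for h in range(2):
            grad[self._i_ls + h] = (
                -self.n + rss[h] / sig[h] ** 2 + 1.0 - 2.0 * sig[h] ** 2 / (sc2 + sig[h] ** 2)
            )
            logp += ls[h] - np.log1p(sig[h] ** 2 / sc2)

        grad_u = np.empty((self.J, q_ := self.q))
        for m in range(q_):
            c = self.Z[:, m] * g_eta
            G = np.bincount(self.groups, weights=c, minlength=self.J)
            grad_u[:, m] = sig_g[m] * G - u[:, m]
            grad[self._i_lsg + m] = (
                sig_g[m] * (u[:, m] @ G) + 1.0 - 2.0 * sig_g[m] ** 2 / (sc2 + sig_g[m] ** 2)
            )
            logp += lsg[m] - np.log1p(sig_g[m] ** 2 / sc2)
            if self.spec.random_means:
                grad[self._i_mu + m] = c.sum() - mu[m] / sn2
                logp += -0.5 * mu[m] ** 2 / sn2
        grad[self._i_u:] = grad_u.ravel()
        logp += -0.5 * np.sum(u * u)
        return logp, grad

    def loglike(self, beta=None, lambda2=1.0, sigma1=1.0, sigma2=1.0,
                gamma=None, mu=None):
        """Exact log-likelihood (with normalizing constants) at a parameter
        point, conditioning on the random effects ``gamma`` (J, q)."""
        beta = np.zeros(self.p) if beta is None else np.asarray(beta, float)
        gamma = np.zeros((self.J, self.q)) if gamma is None else np.asarray(gamma, float)
        if mu is not None:
            gamma = gamma + np.asarray(mu, float)[None, :]
        eta = (self.X @ beta if self.p else 0.0) + np.einsum(
            "nq,nq->n", self.Z, gamma[self.groups])
        ll = 0.0
        for h, (lam, sig) in enumerate(((1.0, sigma1), (lambda2, sigma2))):
            r = self.y[:, h] - lam * eta
            ll += -0.5 * self.n * np.log(2 * np.pi * sig**2) - 0.5 * (r @ r) / sig**2
        return ll

    # ------------------------------------------------------------------ #

    @classmethod
    def from_design(cls, design: DesignMatrix, spec: ModelSpec | None = None):
        """Build the model from a standardized design matrix.

        Moderators listed in the spec enter as fixed-effect two-way
        interactions with each hinge sound term.  Fixed-effect columns that
        are constant in this design (e.g. an unpopulated dummy level in a
        small cohort) are dropped and recorded on ``dropped_columns``.
        """
        spec = spec if spec is not None else ModelSpec()
        df = design.frame
        fixed_names, X, dropped = _fixed_design(df, spec, drop_constant=True)
        Z = _random_design(df, spec)
        model = cls(df[["y1", "y2"]].to_numpy(float), X, Z,
                    df["participant_idx"].to_numpy(int), spec,
                    fixed_names=fixed_names, random_names=list(spec.random_effects),
                    participants=design.participants)
        model.dropped_columns = dropped
        return model

    def _x0(self, rng):
        x0 = rng.normal(0.0, 0.1, self.dim)
        x0[self._i_lam] = 0.5 + 0.2 * rng.normal()
        return x0

    def fit(self, draws: int = 1000, warmup: int = 1000, chains: int = 4,
            seed: int = 0, target_accept: float = 0.95,
            max_leapfrog: int = 32) -> "LatentWellbeingResults":
        """Sample the posterior with HMC; returns a results object."""
        raw, chain_stats = hmc.sample(
            self.logp_grad, self._x0, chains, warmup, draws, seed,
            target_accept=target_accept, max_leapfrog=max_leapfrog)
        divergences = int(sum(r.divergences for r in chain_stats))
        C, D = chains, draws
        post = {}
        if self.p:
            beta_w = raw[:, :, : self.p]
            post["beta"] = np.einsum(
                "pk,cdk->cdp",
                np.linalg.inv(self._R), beta_w) if self.p else beta_w
        else:
            post["beta"] = np.zeros((C, D, 0))
        post["lambda2"] = raw[:, :, self._i_lam]
        post["sigma1"] = np.exp(raw[:, :, self._i_ls])
        post["sigma2"] = np.exp(raw[:, :, self._i_ls + 1])
        post["sigma_gamma"] = np.exp(raw[:, :, self._i_lsg:self._i_lsg + self.q])
        if self.spec.random_means:
            post["mu_gamma"] = raw[:, :, self._i_mu:self._i_mu + self.q]
        u = raw[:, :, self._i_u:].reshape(C, D, self.J, self.q)
        gamma = post["sigma_gamma"][:, :, None, :] * u
        if self.spec.random_means:
            gamma = gamma + post["mu_gamma"][:, :, None, :]
        post["gamma"] = gamma
        return LatentWellbeingResults(self, post, divergences, seed=seed,
                                      warmup=warmup, chain_stats=chain_stats)


def _flatten_posterior(post, fixed_names, random_names, random_means):
    """Named (chain, draw) arrays for every scalar reported parameter."""
    out = {}
    for k, name in enumerate(fixed_names):
        out[f"beta[{name}]"] = post["beta"][:, :, k]
    out["lambda2"] = post["lambda2"]
    out["sigma1"] = post["sigma1"]
    out["sigma2"] = post["sigma2"]
    for m, name in enumerate(random_names):
        out[f"sigma_gamma[{name}]"] = post["sigma_gamma"][:, :, m]
        if random_means:
            out[f"mu_gamma[{name}]"] = post["mu_gamma"][:, :, m]
    return out


def summarize_posterior(named_draws: dict, divergences: int = 0,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-parameter posterior mean, 90% credible interval (5th-95th
    percentile of pooled post-warmup draws), split-R-hat and ESS."""
    rows = []
    for name, arr in named_draws.items():
        a = np.asarray(arr, float)
        if a.ndim == 1:
            a = a[None, :]
        pooled = a.reshape(-1)
        if a.shape[0] >= 2 and a.shape[1] >= 4 and np.ptp(pooled) > 0:
            ds = az.convert_to_dataset(a)
            rhat = float(az.rhat(ds)["x"].values)
            ess = float(az.ess(ds)["x"].values)
        else:
            rhat, ess = np.nan, float(pooled.size)
        rows.append({
            "parameter": name,
            "mean": float(pooled.mean()),
            "ci5": float(np.percentile(pooled, 5)),
            "ci95": float(np.percentile(pooled, 95)),
            "rhat": rhat,
            "ess": ess,
        })
    df = pd.DataFrame(rows).set_index("parameter")
    df.attrs["divergences"] = int(divergences)
    if seed is not None:
        df.attrs["seed"] = int(seed)
    return df


class LatentWellbeingResults:
    """Posterior draws plus diagnostics, summaries and prediction."""

    def __init__(self, model: LatentWellbeingModel, posterior: dict,
                 divergences: int, seed: int, warmup: int, chain_stats=None):
        self.model = model
        self.posterior = posterior
        self.divergences = divergences
        self.seed = seed
        self.warmup = warmup
        self.chain_stats = chain_stats or []
        self.n_chains, self.n_draws = posterior["lambda2"].shape

    # -- diagnostics ---------------------------------------------------- #

    def named_draws(self) -> dict:
        return _flatten_posterior(self.posterior, self.model.fixed_names,
                                  self.model.random_names,
                                  self.model.spec.random_means)

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.named_draws(), self.divergences, self.seed)

    def check_convergence(self, rhat_cutoff: float = 1.1) -> ConvergenceReport:
        s = self.summary()
        max_rhat = float(np.nanmax(s["rhat"])) if s["rhat"].notna().any() else 1.0
        min_ess = float(np.nanmin(s["ess"]))
        passed = (max_rhat < rhat_cutoff) and (self.divergences == 0)
        return ConvergenceReport(passed, max_rhat, self.divergences, min_ess)

    # -- parameter access ------------------------------------------------ #

    def coef_draws(self, name: str) -> np.ndarray:
        """Pooled draws of one fixed-effect coefficient (by design name)."""
        k = self.model.fixed_names.index(name)
        return self.posterior["beta"][:, :, k].reshape(-1)

    def coef(self, name: str) -> float:
        return float(self.coef_draws(name).mean())

    def unstandardize_effect(self, name: str, sound_sd: float,
                             delta: float = 10.0) -> dict:
        """Percent wellbeing change per ``delta`` dBA for a sound coefficient,
        with 90% and 95% credible intervals from the posterior draws."""
        pct = unstandardize_effect(self.coef_draws(name), sound_sd, delta)
        return {
            "mean": float(pct.mean()),
            "ci90": (float(np.percentile(pct, 5)), float(np.percentile(pct, 95))),
            "ci95": (float(np.percentile(pct, 2.5)), float(np.percentile(pct, 97.5))),
        }

    def random_effect_table(self) -> pd.DataFrame:
        """Posterior mean and SD of each participant's coefficients
        (mu + deviation in random-means mode; pure deviations otherwise)."""
        g = self.posterior["gamma"]  # (C, D, J, q)
        mean = g.mean(axis=(0, 1))
        sd = g.std(axis=(0, 1), ddof=1)
        rows = []
        for j, pid in enumerate(self.model.participants):
            for m, name in enumerate(self.model.random_names):
                rows.append({"participant_id": pid, "term": name,
                             "mean": mean[j, m], "sd": sd[j, m]})
        return pd.DataFrame(rows)

    # -- prediction ------------------------------------------------------ #

    def _eta_draws_mean(self, X, Z, groups, weight=None):
        """Posterior mean of (weight * eta) per row, chunked over draws."""
        C, D = self.n_chains, self.n_draws
        beta = self.posterior["beta"].reshape(C * D, -1)
        gamma = self.posterior["gamma"].reshape(C * D, self.model.J, self.model.q)
        w = weight.reshape(C * D) if weight is not None else None
        total = np.zeros(len(X))
        known = groups >= 0
        g_safe = np.where(known, groups, 0)
        for lo in range(0, C * D, 250):
            hi = min(lo + 250, C * D)
            eta = beta[lo:hi] @ X.T if X.shape[1] else np.zeros((hi - lo, len(X)))
            gg = np.einsum("snq,nq->sn", gamma[lo:hi][:, g_safe, :], Z)
            eta = eta + np.where(known[None, :], gg, 0.0)
            if w is not None:
                eta = eta * w[lo:hi, None]
            total += eta.sum(axis=0)
        return total / (C * D)

    def predict(self, design: DesignMatrix,
                params: StandardizationParams | None = None) -> pd.DataFrame:
        """Posterior-mean outcome predictions on natural scales.

        Rows from participants unseen in training get zero random effects.
        """
        params = params if params is not None else design.params
        df = design.frame
        spec = self.model.spec
        _, X, _ = _fixed_design(df, spec, names=self.model.fixed_names)
        Z = _random_design(df, spec)
        # map this design's participants onto the fitted model's codes
        code = {pid: j for j, pid in enumerate(self.model.participants)}
        groups = np.array([code.get(p, -1) for p in df["participant_id"]], int)

        y1_std = self._eta_draws_mean(X, Z, groups)  # lambda1 = 1
        y2_std = self._eta_draws_mean(X, Z, groups,
                                      weight=self.posterior["lambda2"])
        out = pd.DataFrame({
            "participant_id": df["participant_id"].to_numpy(),
            "pred_y1": y1_std,
            "pred_y2": y2_std,
            "sdnn_ms": params.inverse("sdnn", y1_std),
            "nhf": params.inverse("nhf", y2_std),
        }, index=df.index)
        return out

    def fixed_predictor(self, design: DesignMatrix) -> np.ndarray:
        """Posterior-mean latent score per row from fixed effects only
        (random effects subtracted) -- the adjusted wellbeing score."""
        _, X, _ = _fixed_design(design.frame, self.model.spec,
                                names=self.model.fixed_names)
        beta_mean = self.posterior["beta"].reshape(-1, X.shape[1]).mean(axis=0)
        return X @ beta_mean
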