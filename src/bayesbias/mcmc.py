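"""Bayesian bias analysis: random-intercept Poisson MCMC with per-iteration
bias-parameter draws.

The outcome model is a log-link Poisson working likelihood for the binary
outcome with a Gaussian per-subject intercept b_i ~ N(0, tau).  Regression
coefficients get diffuse N(0, 1e6) priors; the precision 1/tau gets a
Gamma(0.001, 0.001) prior and is updated by an exact Gibbs step (it is
conditionally conjugate).  Coefficients and random intercepts are updated
by random-walk Metropolis with step sizes adapted during burn-in only, so
the post-burn-in kernel satisfies detailed balance.

Each retained iteration additionally draws the three bias parameters
(p1, p0, ln rr_uy) from the expert priors — they are not identified by the
data, so they are sampled independently of it — and records the adjusted
risk ratio exp(beta_exposure) / BCF.  Sampling extends past the initial
run until the batch-means Monte Carlo standard error of the adjusted RR
falls below a stated fraction of its posterior SD, or an iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .biascorrect import bcf_array
from .panel_models import DEFAULT_COVARIATES, EXPOSURE_COL, OUTCOME_COL, build_design
from .summaries import PosteriorSummary, mcse

__all__ = [
    "HyperPriors", "McmcConfig", "PointMassBias", "run_bias_mcmc",
    "sample_precision", "mcse", "PosteriorSummary",
]


@dataclass(frozen=True)
class HyperPriors:
    """Diffuse hyperpriors for the outcome model."""

    coef_mean: float = 0.0
    coef_variance: float = 1e6
    precision_shape: float = 0.001
    precision_rate: float = 0.001


@dataclass(frozen=True)
class McmcConfig:
    n_burnin: int = 1000
    n_iter_initial: int = 4000
    n_iter_max: int = 10_000
    mcse_fraction_stop: float = 0.05
    seed: int | None = None
    extend_step: int = 2000

    def __post_init__(self):
        if not 0 < self.mcse_fraction_stop < 1:
            raise ValueError("mcse_fraction_stop must be in (0, 1)")
        if not 0 <= self.n_burnin < self.n_iter_initial:
            raise ValueError("need 0 <= n_burnin < n_iter_initial")
        if self.n_iter_initial > self.n_iter_max:
            raise ValueError("n_iter_initial cannot exceed n_iter_max")


@dataclass(frozen=True)
class PointMassBias:
    """Degenerate bias 'priors' fixed at a single parameter triple.

    Useful for checks: with p1 == p0 the bias correction factor is
    identically 1 and the adjusted posterior coincides with the
    measured-confounder-only posterior draw for draw.
    """

    p1: float
    p0: float
    rr_uy: float

    def draw_bias(self, rng: np.random.Generator, n: int):
        return (np.full(n, self.p1), np.full(n, self.p0), np.full(n, self.rr_uy))


def sample_precision(rng: np.random.Generator, b: np.ndarray,
                     hyper: HyperPriors = HyperPriors()) -> float:
    """Gibbs draw of the random-effect precision 1/tau.

    Full conditional given intercepts b is
    Gamma(shape + n/2, rate + sum(b^2)/2).
    """
    b = np.asarray(b, dtype=float)
    shape = hyper.precision_shape + b.size / 2.0
    rate = hyper.precision_rate + float(b @ b) / 2.0
    return float(rng.gamma(shape, 1.0 / rate))


class _RandomInterceptPoissonSampler:
    """Metropolis-within-Gibbs sampler for the random-intercept model."""

    def __init__(self, X, y, cluster_idx, n_clusters, hyper, rng):
        self.X = X
        self.y = y
        self.idx = cluster_idx
        self.nc = n_clusters
        self.hyper = hyper
        self.rng = rng
        self.p = X.shape[1]
        # state
        try:
            glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            self.beta = np.asarray(glm.params, dtype=float)
            init_se = np.asarray(glm.bse, dtype=float)
            init_se[~np.isfinite(init_se)] = 0.1
        except Exception:
            self.beta = np.zeros(self.p)
            init_se = np.full(self.p, 0.1)
        self.b = np.zeros(n_clusters)
        self.precision = 1.0
        self.eta = X @ self.beta
        self.mu = np.exp(self.eta + self.b[cluster_idx])
        # per-record sums by cluster, reused in the intercept update
        self.y_by_cluster = np.bincount(cluster_idx, weights=y, minlength=n_clusters)
        # adaptation state
        self.step_beta = np.clip(2.4 * init_se, 1e-3, 1.0)
        self.step_b = 0.5
        self.acc_beta = np.zeros(self.p)
        self.acc_b = 0.0
        self.n_adapt = 0

    def _loglik_terms(self, eta_b):
        return self.y * eta_b - np.exp(eta_b)

    def update_beta(self):
        h = self.hyper
        for j in range(self.p):
            delta = self.rng.normal(0.0, self.step_beta[j])
            xj = self.X[:, j]
            d_eta = xj * delta
            mu_new = self.mu * np.exp(d_eta)
            d_ll = float(self.y @ d_eta - (mu_new.sum() - self.mu.sum()))
            bj_new = self.beta[j] + delta
            d_prior = -((bj_new - h.coef_mean) ** 2
                        - (self.beta[j] - h.coef_mean) ** 2) / (2 * h.coef_variance)
            if np.log(self.rng.uniform()) < d_ll + d_prior:
                self.beta[j] = bj_new
                self.eta += d_eta
                self.mu = mu_new
                self.acc_beta[j] += 1

    def update_intercepts(self):
        prop = self.rng.normal(0.0, self.step_b, self.nc)
        mu_sum = np.bincount(self.idx, weights=self.mu, minlength=self.nc)
        d_ll = (self.y_by_cluster * prop
                - mu_sum * (np.exp(prop) - 1.0))
        b_new = self.b + prop
        d_prior = -self.precision * (b_new**2 - self.b**2) / 2.0
        accept = np.log(self.rng.uniform(size=self.nc)) < d_ll + d_prior
        self.b = np.where(accept, b_new, self.b)
        self.acc_b += accept.mean()
        if accept.any():
            self.mu = self.mu * np.exp(np.where(accept, prop, 0.0)[self.idx])

    def update_precision(self):
        self.precision = sample_precision(self.rng, self.b, self.hyper)

    def adapt(self):
        """Robbins-Monro step-size tuning; call during burn-in only."""
        self.n_adapt += 1
        gamma = min(0.25, 2.0 / np.sqrt(self.n_adapt))
        window = 25
        if self.n_adapt % window == 0:
            rates = self.acc_beta / window
            self.step_beta *= np.exp(gamma * (rates - 0.44))
            self.acc_beta[:] = 0.0
            rate_b = self.acc_b / window
            self.step_b *= np.exp(gamma * (rate_b - 0.44))
            self.acc_b = 0.0

    def iterate(self, adapt=False):
        self.update_beta()
        self.update_intercepts()
        self.update_precision()
        if adapt:
            self.adapt()


def run_bias_mcmc(records: pd.DataFrame | None,
                  covariates=DEFAULT_COVARIATES,
                  priors=None,
                  hyper: HyperPriors = HyperPriors(),
                  config: McmcConfig = McmcConfig(),
                  fixed_unadjusted_rr: float | None = None) -> PosteriorSummary:
    """Posterior of the bias-adjusted exposure risk ratio.

    Parameters
    ----------
    records
        Analysis records from :func:`bayesbias.panel_models.build_analysis_records`;
        may be None when ``fixed_unadjusted_rr`` is given (pure prior
        propagation through the same machinery).
    priors
        Anything with ``draw_bias(rng, n)`` (an
        :class:`~bayesbias.priors.ExpertPriorSet` or
        :class:`PointMassBias`); None applies no bias correction, i.e.
        returns the measured-confounder-only posterior.
    fixed_unadjusted_rr
        If given, the per-iteration unadjusted RR is this constant instead
        of ``exp(beta_exposure)``.

    Returns a :class:`PosteriorSummary` whose draws are adjusted RRs;
    ``diagnostics`` carries acceptance rates, the exposure-coefficient and
    random-effect-variance draws, and the stopping trace.
    """
    if records is None and fixed_unadjusted_rr is None:
        raise ValueError("need analysis records or a fixed unadjusted RR")
    if fixed_unadjusted_rr is not None and fixed_unadjusted_rr <= 0:
        raise ValueError("fixed_unadjusted_rr must be positive")

    ss = np.random.SeedSequence(config.seed)
    model_seed, bias_seed = ss.spawn(2)
    rng_bias = np.random.default_rng(bias_seed)

    sampler = None
    if records is not None and fixed_unadjusted_rr is None:
        X = build_design(records, covariates).to_numpy(float)
        y = records[OUTCOME_COL].to_numpy(float)
        codes, _ = pd.factorize(records["subject_id"], sort=False)
        exposure_pos = list(build_design(records, covariates).columns).index(EXPOSURE_COL)
        sampler = _RandomInterceptPoissonSampler(
            X, y, codes, int(codes.max()) + 1, hyper,
            np.random.default_rng(model_seed))
        for _ in range(config.n_burnin):
            sampler.iterate(adapt=True)

    beta_draws: list[float] = []
    tau_draws: list[float] = []

    def run_chunk(n):
        if sampler is None:
            beta_draws.extend([np.log(fixed_unadjusted_rr)] * n)
            tau_draws.extend([np.nan] * n)
            return
        for _ in range(n):
            sampler.iterate(adapt=False)
            beta_draws.append(sampler.beta[exposure_pos])
            tau_draws.append(1.0 / sampler.precision)

    def adjusted_so_far():
        unadj = np.exp(np.asarray(beta_draws))
        if priors is None:
            return unadj
        n = len(beta_draws) - adjusted_so_far.n_bias
        if n > 0:
            p1, p0, rr_uy = priors.draw_bias(rng_bias, n)
            adjusted_so_far.bcf = np.concatenate(
                [adjusted_so_far.bcf, bcf_array(p1, p0, rr_uy)])
            adjusted_so_far.n_bias = len(beta_draws)
        return unadj / adjusted_so_far.bcf

    adjusted_so_far.bcf = np.empty(0)
    adjusted_so_far.n_bias = 0

    run_chunk(config.n_iter_initial)
    trace = []
    while True:
        adjusted = adjusted_so_far()
        err = mcse(adjusted)
        sd = float(np.std(adjusted, ddof=1))
        trace.append({"n_iter": len(adjusted), "mcse": err, "sd": sd})
        converged = sd == 0.0 or err < config.mcse_fraction_stop * sd
        if converged or len(adjusted) >= config.n_iter_max:
            break
        run_chunk(min(config.extend_step, config.n_iter_max - len(adjusted)))

    diagnostics = {
        "stopping_trace": trace,
        "exposure_coef_draws": np.asarray(beta_draws),
        "tau_draws": np.asarray(tau_draws),
        "n_burnin": config.n_burnin,
    }
    if sampler is not None:
        diagnostics["step_beta"] = sampler.step_beta
        diagnostics["step_b"] = sampler.step_b
    summary = PosteriorSummary.from_draws(adjusted, converged=bool(converged),
                                          diagnostics=diagnostics)
    return summary
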