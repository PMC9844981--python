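"""The bias MCMC: MCSE estimator, Gibbs precision step, sampler properties."""

import numpy as np
import pytest
from scipy import stats

from bayesbias import (
    CohortSpec,
    ElicitedInterval,
    HyperPriors,
    McmcConfig,
    PointMassBias,
    build_analysis_records,
    build_expert_prior_set,
    mcse,
    run_bias_mcmc,
    simulate_cohort,
)
from bayesbias.mcmc import sample_precision


class TestMcse:
    def test_iid_draws_match_closed_form(self, rng):
        draws = rng.standard_normal(10_000)
        assert mcse(draws) == pytest.approx(0.01, rel=0.25)

    def test_constant_sequence_is_zero(self):
        assert mcse(np.full(1000, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_ar1_matches_analytic_long_run_variance(self, rng):
        rho, n = 0.5, 200_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        analytic = np.sqrt((1 + rho) / (1 - rho) / n)  # sd of the mean
        assert mcse(x) == pytest.approx(analytic, rel=0.2)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            mcse(np.arange(50))


class TestPrecisionGibbs:
    def test_matches_analytic_gamma_full_conditional(self, rng):
        """Sampled precisions at fixed intercepts follow
        Gamma(shape + n/2, rate + sum(b^2)/2)."""
        hp = HyperPriors()
        b = rng.normal(0, 0.7, 60)
        draws = np.array([sample_precision(rng, b, hp) for _ in range(3000)])
        shape = hp.precision_shape + b.size / 2
        rate = hp.precision_rate + (b @ b) / 2
        _, p = stats.kstest(draws, stats.gamma(shape, scale=1 / rate).cdf)
        assert p > 0.01


class TestConfigValidation:
    def test_burnin_must_precede_initial_run(self):
        with pytest.raises(ValueError):
            McmcConfig(n_burnin=5000, n_iter_initial=4000)

    def test_stop_fraction_in_unit_interval(self):
        with pytest.raises(ValueError):
            McmcConfig(mcse_fraction_stop=1.5)

    def test_initial_cannot_exceed_cap(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter_initial=20_000, n_iter_max=10_000)


@pytest.fixture(scope="module")
def small_records():
    spec = CohortSpec(n_subjects=150, seed=41)
    return build_analysis_records(simulate_cohort(spec).visits)


SHORT = dict(n_burnin=400, n_iter_initial=1200, n_iter_max=1200)


class TestRunBiasMcmc:
    def test_seed_determinism(self, small_records, expert2_priors):
        a = run_bias_mcmc(small_records, covariates=[], priors=expert2_priors,
                          config=McmcConfig(seed=3, **SHORT))
        b = run_bias_mcmc(small_records, covariates=[], priors=expert2_priors,
                          config=McmcConfig(seed=3, **SHORT))
        assert np.array_equal(a.draws, b.draws)

    def test_point_mass_null_equals_uncorrected_draw_for_draw(
            self, small_records):
        """With p1 == p0 the correction factor is exactly 1, so the
        adjusted chain equals the measured-confounder-only chain."""
        null = PointMassBias(0.2, 0.2, 3.0)
        a = run_bias_mcmc(small_records, covariates=[], priors=null,
                          config=McmcConfig(seed=5, **SHORT))
        b = run_bias_mcmc(small_records, covariates=[], priors=None,
                          config=McmcConfig(seed=5, **SHORT))
        assert np.array_equal(a.draws, b.draws)

    def test_chains_from_different_seeds_agree(self, small_records,
                                               expert1_priors):
        runs = [run_bias_mcmc(small_records, covariates=[],
                              priors=expert1_priors,
                              config=McmcConfig(seed=s, n_burnin=500,
                                                n_iter_initial=4000,
                                                n_iter_max=4000))
                for s in (101, 202)]
        combined = np.hypot(runs[0].mcse, runs[1].mcse)
        assert abs(runs[0].median - runs[1].median) < 3 * combined

    def test_monotone_prior_influence(self):
        """A stochastically larger p1 prior pulls the adjusted RR down
        (p0 and rr_uy fixed, rr_uy > 1)."""
        def priors_with_p1(lo, hi):
            return build_expert_prior_set([
                ElicitedInterval("P1", lo, hi),
                ElicitedInterval("P0", 0.05, 0.15),
                ElicitedInterval("RR_UY", 2.0, 3.0),
            ])

        low = run_bias_mcmc(None, priors=priors_with_p1(0.10, 0.20),
                            fixed_unadjusted_rr=1.0,
                            config=McmcConfig(seed=8, n_burnin=0,
                                              n_iter_initial=20_000,
                                              n_iter_max=20_000))
        high = run_bias_mcmc(None, priors=priors_with_p1(0.35, 0.55),
                             fixed_unadjusted_rr=1.0,
                             config=McmcConfig(seed=8, n_burnin=0,
                                               n_iter_initial=20_000,
                                               n_iter_max=20_000))
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(high.draws, q) < np.quantile(low.draws, q)

    def test_mcse_stopping_rule_extends_sampling(self, small_records,
                                                 expert2_priors):
        cfg = McmcConfig(seed=9, n_burnin=200, n_iter_initial=500,
                         n_iter_max=6000, mcse_fraction_stop=0.01,
                         extend_step=500)
        s = run_bias_mcmc(small_records, covariates=[], priors=expert2_priors,
                          config=cfg)
        trace = s.diagnostics["stopping_trace"]
        assert len(trace) > 1  # the strict criterion forced an extension
        assert s.n_iter_used > 500
        if s.converged:
            assert s.mcse < 0.01 * np.std(s.draws, ddof=1)
        else:
            assert s.n_iter_used == 6000

    def test_posterior_recovers_known_adjusted_rr(self, expert2_priors):
        """Cohorts generated with a real confounder at the priors' typical
        values: adjusted posteriors centre on the true conditional RR 0.82
        and their credible intervals usually cover it."""
        medians, covers = [], 0
        for seed in (17, 18, 19, 20):
            spec = CohortSpec(n_subjects=500, seed=seed)  # RR 0.82, BCF 1.17
            rec = build_analysis_records(simulate_cohort(spec).visits)
            s = run_bias_mcmc(rec, covariates=[], priors=expert2_priors,
                              config=McmcConfig(seed=seed + 100))
            medians.append(s.median)
            covers += s.ci95[0] <= 0.82 <= s.ci95[1]
        # single-cohort medians scatter with sd ~0.07 around the truth
        assert np.mean(medians) == pytest.approx(0.82, abs=0.11)
        assert covers >= 3

    def test_requires_records_or_fixed_rr(self, expert2_priors):
        with pytest.raises(ValueError, match="records"):
            run_bias_mcmc(None, priors=expert2_priors)
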