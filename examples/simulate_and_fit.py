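"""Simulate a cohort with a known confounder and fit the panel models.

The default generator produces ~601 subjects with a mean of 4.3 quarterly
visits, 65.9% baseline exposure, a latent confounder at (p1=0.30,
p0=0.15, rr_uy=2.35) and a true conditional exposure RR of 0.82 — so the
confounder-blind analysis should land near 0.82 x 1.17 = 0.96.
"""

import numpy as np

from bayesbias import (
    CohortSpec,
    build_analysis_records,
    empirical_bias_check,
    fit_gee_poisson,
    fit_re_poisson_ml,
    simulate_cohort,
)

cohort = simulate_cohort(CohortSpec(seed=20260901))
visits = cohort.visits
print(f"{visits.subject_id.nunique()} subjects, "
      f"{visits.groupby('subject_id').size().mean():.1f} visits on average, "
      f"{100 * visits.query('visit_index == 0').unsafe_injection.mean():.1f}% "
      "baseline exposure")

records = build_analysis_records(visits)
print(f"{len(records)} lagged exposure->outcome records after censoring")

gee = fit_gee_poisson(records)
re = fit_re_poisson_ml(records)
print(f"GEE (marginal) RR: {gee.exposure_rr:.2f} "
      f"(95% CI {gee.ci95[0]:.2f}-{gee.ci95[1]:.2f})")
print(f"random-intercept ML (conditional) RR: {re.exposure_rr:.2f}")

rep = empirical_bias_check(cohort)
print(f"latent truth: crude RR {rep['crude_rr']:.2f}, "
      f"U-adjusted RR {rep['adjusted_rr']:.2f}, "
      f"realized bias factor {rep['realized_bcf']:.2f}")

# The two fitted RRs agree (the risk ratio is collapsible here) and sit
# near 0.96; only the latent U-adjusted RR reveals the true 0.82.
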