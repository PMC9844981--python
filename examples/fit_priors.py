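"""Fit bias-parameter priors from two experts' 95% intervals.

Each expert states an interval for P1 (confounder prevalence among the
exposed), P0 (among the unexposed), and RR_UY (confounder-outcome risk
ratio).  Proportions get percentile-matched beta priors; the risk ratio
gets a normal prior on the log scale.
"""

from bayesbias import fit_experts

CONFIG = {
    "experts": [
        {"expert_id": "expert 1",
         "intervals": {"P1": [0.025, 0.095], "P0": [0.01, 0.06],
                       "RR_UY": [1.1, 2.2]}},
        {"expert_id": "expert 2",
         "intervals": {"P1": [0.20, 0.40], "P0": [0.10, 0.20],
                       "RR_UY": [1.1, 5.0]}},
    ]
}

for ps in fit_experts(CONFIG):
    print(f"{ps.expert_id}:")
    p1_lo, p1_hi = ps.p1_prior.interval95()
    p0_lo, p0_hi = ps.p0_prior.interval95()
    print(f"  P1 ~ Beta({ps.p1_prior.alpha:.2f}, {ps.p1_prior.beta:.2f})"
          f"  -> 95% interval ({p1_lo:.3f}, {p1_hi:.3f})")
    print(f"  P0 ~ Beta({ps.p0_prior.alpha:.2f}, {ps.p0_prior.beta:.2f})"
          f"  -> 95% interval ({p0_lo:.3f}, {p0_hi:.3f})")
    print(f"  ln RR_UY ~ Normal({ps.log_rr_prior.mu:.2f}, "
          f"{ps.log_rr_prior.sigma:.2f})")

# The fitted 2.5th/97.5th percentiles reproduce each stated interval, so a
# draw from the prior falls inside the expert's interval 95% of the time.
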