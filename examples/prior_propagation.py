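"""Prior-only Monte Carlo propagation of bias-parameter uncertainty.

Holding the unadjusted RR fixed at 0.96, draw the three bias parameters
from each expert's fitted priors and summarise the distribution of the
adjusted RR.  This isolates how much of the final uncertainty comes from
the priors alone.
"""

from bayesbias import fit_experts, monte_carlo_adjust

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

for priors in fit_experts(CONFIG):
    s = monte_carlo_adjust(0.96, priors, n_draws=100_000, seed=1)
    print(f"{priors.expert_id}: adjusted RR median {s.median:.2f}, "
          f"95% interval ({s.ci95[0]:.2f}, {s.ci95[1]:.2f}), "
          f"MCSE {s.mcse:.4f}")

# Expert 1's tight priors barely move the estimate (~0.95); expert 2's
# wider, larger bias parameters pull it down to ~0.83 with a much wider
# interval.
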