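"""Deterministic plug-in bias correction.

Typical bias-parameter values (arithmetic means of the prevalence interval
limits, geometric mean of the risk-ratio limits) give a single bias
correction factor; dividing the measured-confounder-only RR by it yields
the fully adjusted RR.
"""

from bayesbias import (
    ElicitedInterval,
    adjust_rr,
    build_expert_prior_set,
    typical_values,
)

priors = build_expert_prior_set([
    ElicitedInterval("P1", 0.20, 0.40),
    ElicitedInterval("P0", 0.10, 0.20),
    ElicitedInterval("RR_UY", 1.1, 5.0),
], expert_id="expert 2")

tv = typical_values(priors)
result = adjust_rr(0.96, tv)

print(f"typical values: P1={tv.p1:.2f}, P0={tv.p0:.2f}, RR_UY={tv.rr_uy:.2f}")
print(f"bias correction factor = {result.bcf:.2f}")
print(f"adjusted RR = {result.unadjusted_rr:.2f} / {result.bcf:.2f} "
      f"= {result.adjusted_rr:.2f}")

# An unadjusted RR of 0.96 (no association) becomes 0.82 once the
# confounder is accounted for: the exposed are MORE likely to get tested.
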