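"""Bias-correction arithmetic for a single binary unmeasured confounder.

For a binary confounder U with prevalence ``p1`` among the exposed, ``p0``
among the unexposed, and risk ratio ``rr_uy`` on the outcome, omitting U
multiplies the exposure risk ratio by the bias correction factor

    BCF = (rr_uy * p1 + 1 - p1) / (rr_uy * p0 + 1 - p0)

so the confounder-adjusted risk ratio is the unadjusted (measured-
confounder-only) risk ratio divided by the BCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .priors import ExpertPriorSet
from .summaries import PosteriorSummary


@dataclass(frozen=True)
class BiasParameters:
    """A realized triple of bias parameters."""

    p1: float
    p0: float
    rr_uy: float

    def __post_init__(self):
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1):
            raise ValueError("p0 and p1 must be proportions in [0, 1]")
        if self.rr_uy <= 0:
            raise ValueError("rr_uy must be positive")


@dataclass(frozen=True)
class CorrectionResult:
    bcf: float
    unadjusted_rr: float
    adjusted_rr: float


def bcf_array(p1, p0, rr_uy):
    """Vectorized bias correction factor; inputs broadcast."""
    p1, p0, rr_uy = np.asarray(p1), np.asarray(p0), np.asarray(rr_uy)
    return (rr_uy * p1 + 1.0 - p1) / (rr_uy * p0 + 1.0 - p0)


def bias_correction_factor(bp: BiasParameters) -> float:
    return float(bcf_array(bp.p1, bp.p0, bp.rr_uy))


def adjust_rr(unadjusted_rr: float, bp: BiasParameters) -> CorrectionResult:
    """Divide the measured-confounder-only RR by the bias correction factor."""
    if unadjusted_rr <= 0:
        raise ValueError("unadjusted_rr must be positive")
    bcf = bias_correction_factor(bp)
    return CorrectionResult(bcf=bcf, unadjusted_rr=unadjusted_rr,
                            adjusted_rr=unadjusted_rr / bcf)


def typical_values(priors: ExpertPriorSet) -> BiasParameters:
    """Plug-in bias parameters from the expert's raw interval endpoints.

    Arithmetic mean of the limits for the two prevalences; geometric mean
    for the risk ratio.  Defined on the elicited intervals themselves, so
    the prior set must retain them.
    """
    try:
        iv_p1 = priors.intervals["P1"]
        iv_p0 = priors.intervals["P0"]
        iv_rr = priors.intervals["RR_UY"]
    except KeyError as exc:
        raise ValueError(
            "typical_values needs the elicited intervals retained on the "
            "prior set"
        ) from exc
    return BiasParameters(
        p1=(iv_p1.lower + iv_p1.upper) / 2,
        p0=(iv_p0.lower + iv_p0.upper) / 2,
        rr_uy=float(np.sqrt(iv_rr.lower * iv_rr.upper)),
    )


def monte_carlo_adjust(unadjusted_rr: float, priors: ExpertPriorSet,
                       n_draws: int = 100_000, seed=None) -> PosteriorSummary:
    """Prior-only uncertainty propagation at a fixed unadjusted RR.

    Draws (p1, p0, ln rr_uy) independently from the fitted priors, divides
    the fixed unadjusted RR by the per-draw bias correction factor and
    summarises the resulting distribution (median, 2.5/97.5 percentiles,
    batch-means MCSE).  Reproducible under a fixed seed.
    """
    if unadjusted_rr <= 0:
        raise ValueError("unadjusted_rr must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    if n_draws < 1000:
        warnings.warn(
            f"n_draws={n_draws} is small; percentile summaries will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    p1, p0, rr_uy = priors.draw_bias(rng, n_draws)
    adjusted = unadjusted_rr / bcf_array(p1, p0, rr_uy)
    return PosteriorSummary.from_draws(
        adjusted, converged=True,
        diagnostics={"kind": "prior_propagation", "n_draws": int(n_draws),
                     "unadjusted_rr": float(unadjusted_rr),
                     "expert_id": priors.expert_id},
    )
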