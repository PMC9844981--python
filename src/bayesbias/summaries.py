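"""Posterior summaries shared by the Monte Carlo and MCMC machinery."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def mcse(draws) -> float:
    """Batch-means Monte Carlo standard error of the mean of ``draws``.

    The draw sequence is split into ``floor(sqrt(n))`` consecutive batches;
    the MCSE is the standard deviation of the batch means divided by the
    square root of the number of batches.  Consecutive batches absorb the
    autocorrelation of an MCMC chain, so no thinning is needed.
    """
    draws = np.asarray(draws, dtype=float)
    n = draws.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for a batch-means MCSE, got {n}")
    n_batches = int(np.floor(np.sqrt(n)))
    batch_size = n // n_batches
    trimmed = draws[: n_batches * batch_size].reshape(n_batches, batch_size)
    batch_means = trimmed.mean(axis=1)
    return float(np.std(batch_means, ddof=1) / np.sqrt(n_batches))


@dataclass
class PosteriorSummary:
    """Draws of a scalar quantity plus percentile summaries.

    ``ci95`` holds the 2.5th and 97.5th percentiles (equal-tailed interval;
    a credible interval when the draws are posterior samples).  Percentiles
    use the linear-interpolation (type 7) quantile convention.
    """

    draws: np.ndarray
    median: float
    ci95: tuple[float, float]
    mcse: float
    n_iter_used: int
    converged: bool | None = None
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_draws(cls, draws, converged: bool | None = None,
                   diagnostics: dict | None = None) -> "PosteriorSummary":
        draws = np.asarray(draws, dtype=float)
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        return cls(
            draws=draws,
            median=float(med),
            ci95=(float(lo), float(hi)),
            mcse=mcse(draws),
            n_iter_used=int(draws.size),
            converged=converged,
            diagnostics=diagnostics or {},
        )

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.median <= hi):
            raise ValueError("credible interval must bracket the median")
        if self.mcse < 0:
            raise ValueError("mcse must be nonnegative")
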