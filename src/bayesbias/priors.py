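"""Expert prior elicitation for the three unmeasured-confounding bias parameters.

An expert states a 95% prior interval for each of

* ``P1`` — prevalence of the unmeasured confounder among the exposed,
* ``P0`` — prevalence among the unexposed,
* ``RR_UY`` — risk ratio of the confounder on the outcome.

The two proportions get beta priors whose 2.5th/97.5th percentiles are
matched to the stated interval (grid search plus derivative-free local
refinement); the risk ratio gets a normal prior on the log scale with
mean the midpoint of the log limits and standard deviation their log
range divided by 3.92 (= 2 x 1.96).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, stats

PARAMETER_NAMES = ("P1", "P0", "RR_UY")

#: default tolerance, on the probability scale, for the percentile match
DEFAULT_FIT_TOLERANCE = 1e-3

_GRID_BOUNDS = (0.5, 5000.0)
_GRID_POINTS = 80


@dataclass(frozen=True)
class ElicitedInterval:
    """One expert's 95% prior interval for one bias parameter."""

    parameter_name: str
    lower: float
    upper: float
    expert_id: str = ""

    def __post_init__(self):
        if self.parameter_name not in PARAMETER_NAMES:
            raise ValueError(
                f"parameter_name must be one of {PARAMETER_NAMES}, "
                f"got {self.parameter_name!r}"
            )
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"need 0 < lower < upper, got ({self.lower}, {self.upper}) "
                f"for {self.parameter_name}"
            )
        if self.parameter_name in ("P1", "P0") and not self.upper < 1:
            raise ValueError(
                f"proportion interval must lie inside (0, 1), got upper="
                f"{self.upper} for {self.parameter_name}"
            )


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta distribution parameters must be positive")

    def interval95(self) -> tuple[float, float]:
        """2.5th and 97.5th percentiles of the fitted beta distribution."""
        return tuple(stats.beta.ppf([0.025, 0.975], self.alpha, self.beta))


@dataclass(frozen=True)
class NormalParams:
    """Normal prior for the log risk ratio of the confounder on the outcome."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def interval95_rr(self) -> tuple[float, float]:
        """Implied 95% interval back on the risk-ratio scale."""
        half = 1.96 * self.sigma
        return (float(np.exp(self.mu - half)), float(np.exp(self.mu + half)))


def _percentile_gap(log_ab: np.ndarray, lower: float, upper: float) -> float:
    a, b = np.exp(log_ab)
    lo_b, hi_b = _GRID_BOUNDS
    if not (lo_b <= a <= hi_b and lo_b <= b <= hi_b):
        return 1e6  # keep the refinement inside the declared search domain
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return (lo - lower) ** 2 + (hi - upper) ** 2


def fit_beta_from_interval(interval: ElicitedInterval,
                           tolerance: float = DEFAULT_FIT_TOLERANCE) -> BetaParams:
    """Match a beta distribution's 2.5th/97.5th percentiles to the interval.

    A coarse log-spaced grid over (alpha, beta) in [0.5, 5000]^2 locates a
    starting point; Nelder-Mead then minimises the sum of squared percentile
    errors.  The search is fully deterministic.

    Raises
    ------
    ValueError
        If the interval is not a proportion interval.
    RuntimeError
        If no (alpha, beta) within the search domain matches the interval
        to ``tolerance`` on the probability scale.
    """
    if interval.parameter_name not in ("P1", "P0"):
        raise ValueError(
            "beta fitting applies to the proportion parameters P1/P0, "
            f"got {interval.parameter_name}"
        )
    lower, upper = interval.lower, interval.upper

    grid = np.geomspace(*_GRID_BOUNDS, _GRID_POINTS)
    aa, bb = np.meshgrid(grid, grid, indexing="ij")
    lo = stats.beta.ppf(0.025, aa, bb)
    hi = stats.beta.ppf(0.975, aa, bb)
    sse = (lo - lower) ** 2 + (hi - upper) ** 2
    i, j = np.unravel_index(np.argmin(sse), sse.shape)

    res = optimize.minimize(
        _percentile_gap,
        x0=np.log([grid[i], grid[j]]),
        args=(lower, upper),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 4000},
    )
    params = BetaParams(*np.exp(res.x))
    fit_lo, fit_hi = params.interval95()
    if abs(fit_lo - lower) > tolerance or abs(fit_hi - upper) > tolerance:
        raise RuntimeError(
            f"no beta distribution matches the interval ({lower}, {upper}) "
            f"for {interval.parameter_name} within tolerance {tolerance} "
            f"(best fit: alpha={params.alpha:.4g}, beta={params.beta:.4g}, "
            f"percentiles=({fit_lo:.4g}, {fit_hi:.4g}))"
        )
    return params


def fit_lognormal_rr_from_interval(interval: ElicitedInterval) -> NormalParams:
    """Normal prior for ln(RR_UY) from a 95% interval on the ratio scale.

    mu is the mean of the log limits; sigma is the log range divided by
    3.92, i.e. the normal distribution whose central 95% mass spans the
    stated interval.
    """
    log_lo, log_hi = np.log(interval.lower), np.log(interval.upper)
    return NormalParams(mu=float((log_lo + log_hi) / 2),
                        sigma=float((log_hi - log_lo) / 3.92))


@dataclass(frozen=True)
class ExpertPriorSet:
    """The three fitted bias-parameter priors for one expert.

    The originating elicited intervals are retained: the typical-value
    plug-in is defined on interval endpoints, not on the fitted
    distributions.
    """

    expert_id: str
    p1_prior: BetaParams
    p0_prior: BetaParams
    log_rr_prior: NormalParams
    intervals: dict = field(default_factory=dict)

    def draw_bias(self, rng: np.random.Generator, n: int):
        """Draw ``n`` independent (p1, p0, rr_uy) triples from the priors."""
        p1 = rng.beta(self.p1_prior.alpha, self.p1_prior.beta, n)
        p0 = rng.beta(self.p0_prior.alpha, self.p0_prior.beta, n)
        rr_uy = np.exp(rng.normal(self.log_rr_prior.mu, self.log_rr_prior.sigma, n))
        return p1, p0, rr_uy

    def to_dict(self) -> dict:
        return {
            "expert_id": self.expert_id,
            "p1_prior": {"alpha": self.p1_prior.alpha, "beta": self.p1_prior.beta},
            "p0_prior": {"alpha": self.p0_prior.alpha, "beta": self.p0_prior.beta},
            "log_rr_prior": {"mu": self.log_rr_prior.mu,
                             "sigma": self.log_rr_prior.sigma},
            "intervals": {
                name: [iv.lower, iv.upper] for name, iv in self.intervals.items()
            },
        }


def build_expert_prior_set(intervals, expert_id: str = "",
                           tolerance: float = DEFAULT_FIT_TOLERANCE) -> ExpertPriorSet:
    """Fit all three priors for one expert from exactly one interval each."""
    by_name = {}
    for iv in intervals:
        if iv.parameter_name in by_name:
            raise ValueError(f"duplicated interval for {iv.parameter_name}")
        by_name[iv.parameter_name] = iv
    missing = set(PARAMETER_NAMES) - set(by_name)
    if missing:
        raise ValueError(f"missing interval(s) for {sorted(missing)}")
    return ExpertPriorSet(
        expert_id=expert_id or by_name["P1"].expert_id,
        p1_prior=fit_beta_from_interval(by_name["P1"], tolerance),
        p0_prior=fit_beta_from_interval(by_name["P0"], tolerance),
        log_rr_prior=fit_lognormal_rr_from_interval(by_name["RR_UY"]),
        intervals=by_name,
    )


def load_expert_intervals(source) -> list[list[ElicitedInterval]]:
    """Read per-expert elicited intervals from a YAML/JSON config.

    Expected structure::

        experts:
          - expert_id: "expert 1"
            intervals: {P1: [0.025, 0.095], P0: [0.01, 0.06], RR_UY: [1.1, 2.2]}

    ``source`` may be a path or an already-parsed dict.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        config = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        config = source
    if not isinstance(config, dict) or "experts" not in config:
        raise ValueError("prior config must contain an 'experts' list")
    out = []
    for block in config["experts"]:
        expert_id = str(block.get("expert_id", ""))
        ivs = [
            ElicitedInterval(name, float(lo), float(hi), expert_id)
            for name, (lo, hi) in block["intervals"].items()
        ]
        out.append(ivs)
    return out


def fit_experts(source, tolerance: float = DEFAULT_FIT_TOLERANCE) -> list[ExpertPriorSet]:
    """Load a config and fit an :class:`ExpertPriorSet` per expert."""
    return [
        build_expert_prior_set(ivs, tolerance=tolerance)
        for ivs in load_expert_intervals(source)
    ]


def save_prior_sets(prior_sets, path) -> None:
    Path(path).write_text(
        json.dumps([ps.to_dict() for ps in prior_sets], indent=2) + "\n"
    )
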