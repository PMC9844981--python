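# Methods

## Setting and causal structure

A longitudinal cohort of HIV-negative people who inject drugs is
interviewed quarterly. Exposure E(t) is unsafe injection (sharing,
reusing or borrowing used equipment) in the three months before visit
t; the outcome D(t+1) is not having been HIV-tested by the next visit
(NBT). Measured confounders L are age, gender, education, incarceration
(at baseline and recently) and having ever tested at baseline. The
unmeasured confounder U is insufficient knowledge of HIV transmission
routes: it raises the probability of unsafe injection and lowers the
probability of seeking a test, so it is a common cause of E and D.
Because each subject contributes several (E(t), D(t+1)) pairs, all
models cluster on subject.

## Prior elicitation

Each expert supplies a 95% prior interval for three bias parameters:
P₁ = Pr(U=1 | exposed), P₀ = Pr(U=1 | unexposed), and RR_UY, the risk
ratio of U on the outcome.

* **Proportions.** A beta distribution is fitted so that its 2.5th and
  97.5th percentiles equal the stated limits. The fit minimises the sum
  of squared percentile errors over an 80×80 log-spaced grid of
  (α, β) ∈ [0.5, 5000]², then refines by Nelder–Mead from the best grid
  point. The default acceptance tolerance is 1e-3 on the probability
  scale (the refined fit typically lands within ~1e-8); intervals whose
  match would require parameters outside the search domain are rejected
  with an explicit error rather than extrapolated. Percentile matching
  is a two-equation/two-unknown problem, so the solution is unique and
  the procedure deterministic.
* **Risk ratio.** ln RR_UY gets a normal prior with μ the mean of the
  log limits and σ the log range divided by 3.92 (= 2×1.96), i.e. the
  normal whose central 95% mass spans the interval exactly.

Experts are kept separate throughout; pooling elicitations is out of
scope. The fitted prior set retains its source intervals because the
typical-value plug-in (below) is defined on interval endpoints, not on
fitted distributions.

## Bias correction

For a binary U independent of L within exposure strata,

BCF = (RR_UY·P₁ + 1 − P₁) / (RR_UY·P₀ + 1 − P₀),
adjusted RR = unadjusted RR / BCF.

The formula assumes a single common RR_UY in both exposure strata.
Three usage modes:

1. **Plug-in** at "typical values": arithmetic means of the P₁/P₀
   interval limits and the geometric mean of the RR_UY limits.
2. **Prior-only Monte Carlo**: with the unadjusted RR held fixed, draw
   (P₁, P₀, ln RR_UY) independently from the fitted priors (no
   correlation structure is elicited, so none is imposed) and
   summarise adjusted-RR draws by median and 2.5/97.5 percentiles.
   Percentiles use the linear-interpolation (type 7) convention. Note
   the Monte Carlo median exceeds the plug-in value slightly: the BCF
   is a ratio with the P₀ term in the denominator, so its distribution
   is right-skewed and its median is below the BCF at the componentwise
   typical values.
3. **Full Bayesian analysis** (next section), which also propagates the
   likelihood uncertainty in the unadjusted RR.

## Outcome model and sampler

The outcome is binary but modelled with a log-link Poisson working
likelihood so the exposure coefficient is a log *risk ratio* directly
(the standard modified-Poisson device; log-binomial fits often fail to
converge). Conditional model:

y_ij ~ Poisson(μ_ij), log μ_ij = x_ij'β + b_i, b_i ~ N(0, τ).

Priors: β_k ~ N(0, 10⁶); 1/τ ~ Gamma(0.001, 0.001) (conditionally
conjugate). The sampler is Metropolis-within-Gibbs:

* coefficients: componentwise Gaussian random-walk Metropolis, step
  sizes initialised at 2.4× the GLM standard errors;
* random intercepts: one vectorised random-walk proposal per subject,
  accepted subject-wise;
* precision: exact Gibbs draw from Gamma(shape + n/2, rate + Σb²/2).

Step sizes adapt toward 44% acceptance by Robbins–Monro during burn-in
only and are frozen afterwards, so the post-burn-in kernel satisfies
detailed balance. Defaults mirror the stated procedure: 1000 burn-in
iterations, an initial 4000 retained iterations, then extension in
blocks of 2000 until the batch-means MCSE of the adjusted RR is below
5% of its posterior SD, capped at 10 000 retained iterations (the
summary then carries `converged=False` plus the stopping trace). No
thinning: batch means absorb autocorrelation.

Per retained iteration the bias parameters are drawn from the expert
priors — they are not identified by the likelihood, so they are sampled
independently of the data — and the recorded draw is
exp(β_exposure)/BCF. The RR is collapsible over the shared intercept in
this design, so the conditional exposure coefficient is the quantity
being corrected; the GEE marginal estimate agrees with it (verified in
tests). Two independent seed streams drive the model chain and the bias
draws, so a degenerate bias prior reproduces the uncorrected chain draw
for draw.

MCSE uses batch means with ⌊√n⌋ batches; it requires ≥100 draws.

## Frequentist panel fits

Record construction pairs consecutive visits within subject (exposure
and covariates at t, outcome at t+1), censors at the first
HIV-positive visit, rejects unsorted or duplicated visit indices, and
drops records with missing exposure/outcome listwise (counts reported
in `DataFrame.attrs`). `fit_gee_poisson` wraps statsmodels GEE
(Poisson family, log link, cluster-robust sandwich); the working
correlation defaults to exchangeable, with independence as an option.
`fit_re_poisson_ml` is a maximum-likelihood Gaussian random-intercept
Poisson fit written here (no installed package provides one): the
intercept is integrated out with 25-point Gauss–Hermite quadrature and
(β, σ) maximised by L-BFGS-B with σ bounded at 0; at a boundary
solution the β are replaced by the exact Poisson-GLM ML, to which the
profile likelihood reduces. Standard errors come from the numerical
observed information.

## Synthetic cohort generator

The generator's defaults are the published cohort's structure:

| quantity | default | source/rationale |
|---|---|---|
| subjects | 601 | cohort size |
| visits per subject | 1 + NegBin(size 0.194, mean 3.3), capped at 60 | matches mean 4.3, SD 7.7 (strongly overdispersed) |
| gender / education / incarceration / ever-tested mix | margins of the printed baseline table | cohort composition |
| age | N(23.6, 3.4²) years | cohort composition |
| baseline exposure prevalence | 0.659 | printed baseline figure |
| exposure persistence | 0.85 per visit | chosen once; re-entry rate solved so prevalence is stationary |
| P₁, P₀, RR_UY | 0.30, 0.15, 2.35 | typical values of the wider expert's priors (implied BCF 1.17) |
| true conditional exposure RR | 0.82 | so the U-blind RR lands near 0.96 |
| baseline per-interval NBT risk | 0.25 | keeps log-link risks < 1 (below) |
| random-intercept SD | 0.20 | modest within-subject clustering |
| per-visit seroconversion | 0.01 | rare censoring events |

U is redrawn every visit given current exposure (an optional
exposure→U feedback switch exists but is off: treating U as affected by
prior exposure requires g-methods, which are out of scope). Covariate
effects on the outcome default to zero so that the marginal/conditional
contrast is driven only by U and the intercept; they are configurable.
The outcome at visit t+1 follows the log-link risk model
baseline × trueRR^E(t) × RR_UY^U(t) × exp(x'γ + b_i), truncated at 1;
generation fails if more than 0.1% of risks truncate. This truncation
is why the default baseline risk (0.25) is lower than a realistic NBT
prevalence: a common outcome with RR_UY = 2.35 cannot stay below risk
1 under a log link. Consequences: the generator reproduces the
cohort's *structure* and confounding geometry, not its outcome
prevalence or any recall/social-desirability error in self-reports, so
passing tests certify the estimators' behaviour under the assumed
model, not agreement with the real study's data.

Key self-consistency property (tested): because U enters
multiplicatively and independently of b_i, omitting U from the
conditional model changes the exposure coefficient by exactly log BCF —
the generator's crude/U-adjusted gap converges to the closed-form
factor as the cohort grows.

## Verification experiment sizes

Chosen as the package's own defaults for routine runs: GEE CI coverage
uses 500 replicates of 150-subject cohorts; Bayesian calibration of the
bias MCMC uses 200 replicates of 200-subject cohorts with 500 + 1500
iterations, drawing each replicate's true bias parameters from the
expert priors (the design under which 95% credible-interval coverage
is exactly nominal when the model is true). The calibration replicates
use a lower baseline risk (0.08) and intercept SD (0.15) so that even
large prior draws of RR_UY keep all risks below 1. Recovery of a ratio
parameter is assessed on the log scale; on the raw RR scale the mean of
noisy per-replicate medians is inflated by exp-Jensen.

## Known limitations

* One binary unmeasured confounder with a common RR_UY across exposure
  strata; multiple or continuous confounders are not supported.
* Bias parameters are treated as time-constant and independent of the
  data; there is no exposure–confounder feedback correction.
* The Poisson working likelihood slightly overstates the binomial
  outcome variance, making the likelihood component of posterior
  intervals mildly conservative.
* Expert priors are analysed one expert at a time; no pooling or
  conflict resolution between discordant experts.
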