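"""Conventional frequentist analysis of the lagged longitudinal panel.

The visit table has one row per subject-visit.  Analysis records pair the
exposure (unsafe injection) at visit t with the outcome (not being tested
for HIV, NBT) at visit t+1, censoring each subject at their first
HIV-positive visit.  The exposure risk ratio is then estimated with a
log-link Poisson working model: marginally via GEE with a cluster-robust
sandwich variance, or conditionally via a maximum-likelihood Gaussian
random-intercept Poisson fit (Gauss-Hermite quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import logsumexp

VISIT_COLUMNS = [
    "subject_id", "visit_index", "unsafe_injection", "nbt", "hiv_positive",
    "gender", "age", "education", "incarcerated_baseline",
    "incarcerated_recent", "ever_tested_baseline",
]

#: covariates adjusted for in the fits; gender expands to indicator columns
#: with male as the reference level.
DEFAULT_COVARIATES = [
    "age", "gender", "education", "incarcerated_baseline",
    "incarcerated_recent", "ever_tested_baseline",
]

EXPOSURE_COL = "exposure_lagged"
OUTCOME_COL = "outcome"


@dataclass
class FrequentistFit:
    """Fitted exposure risk ratio with its variance and provenance."""

    params: pd.Series
    cov: pd.DataFrame
    exposure_rr: float
    exposure_se: float  # on the log-RR scale
    ci95: tuple[float, float]
    n_subjects: int
    n_records: int
    model: str
    extra: dict = field(default_factory=dict)


def build_analysis_records(visits: pd.DataFrame) -> pd.DataFrame:
    """Lag, censor and pair the visit rows into analysis records.

    Per subject: visits at or after the first HIV-positive flag are
    discarded; each remaining consecutive visit pair (t, t+1) contributes
    one record with the exposure taken at t, the outcome at t+1, and the
    covariates at t.  Rows with missing exposure or outcome are dropped
    listwise (counts in ``.attrs``); subjects with fewer than two usable
    visits contribute nothing.
    """
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"visit table is missing columns {missing}")

    chunks = []
    n_dropped_missing = 0
    for sid, grp in visits.groupby("subject_id", sort=False):
        vi = grp["visit_index"].to_numpy()
        if len(vi) > 1 and not np.all(np.diff(vi) > 0):
            raise ValueError(
                f"visit_index must be strictly increasing within subject "
                f"{sid!r} (got {vi.tolist()})"
            )
        pos = np.flatnonzero(grp["hiv_positive"].to_numpy() == 1)
        if pos.size:
            grp = grp.iloc[: pos[0]]
        if len(grp) < 2:
            continue
        now, nxt = grp.iloc[:-1], grp.iloc[1:]
        rec = now[["subject_id", "visit_index", "gender", "age", "education",
                   "incarcerated_baseline", "incarcerated_recent",
                   "ever_tested_baseline"]].copy()
        rec[EXPOSURE_COL] = now["unsafe_injection"].to_numpy()
        rec[OUTCOME_COL] = nxt["nbt"].to_numpy()
        ok = rec[EXPOSURE_COL].notna() & rec[OUTCOME_COL].notna()
        n_dropped_missing += int((~ok).sum())
        chunks.append(rec[ok])

    if chunks:
        records = pd.concat(chunks, ignore_index=True)
        records[EXPOSURE_COL] = records[EXPOSURE_COL].astype(int)
        records[OUTCOME_COL] = records[OUTCOME_COL].astype(int)
    else:
        records = pd.DataFrame(
            columns=["subject_id", "visit_index", "gender", "age",
                     "education", "incarcerated_baseline",
                     "incarcerated_recent", "ever_tested_baseline",
                     EXPOSURE_COL, OUTCOME_COL]
        )
    records.attrs["n_dropped_missing"] = n_dropped_missing
    return records


def build_design(records: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Design matrix: intercept, exposure, then the covariate columns.

    ``gender`` expands to female/transgender indicators (male reference);
    all other covariates enter as given.
    """
    cols = {"const": np.ones(len(records)),
            EXPOSURE_COL: records[EXPOSURE_COL].to_numpy(float)}
    for cov in covariates:
        if cov == "gender":
            g = records["gender"].astype(str)
            cols["gender_female"] = (g == "female").to_numpy(float)
            cols["gender_transgender"] = (g == "transgender").to_numpy(float)
        else:
            cols[cov] = records[cov].to_numpy(float)
    X = pd.DataFrame(cols, index=records.index)
    # drop constant indicator columns (e.g. no transgender subjects sampled)
    keep = [c for c in X.columns
            if c == "const" or X[c].nunique() > 1]
    X = X[keep]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient for covariates "
                         f"{list(X.columns)}")
    return X


def _check_records(records: pd.DataFrame):
    groups = records["subject_id"]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 subjects (clusters) to fit")


def fit_gee_poisson(records: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                    working_correlation: str = "exchangeable") -> FrequentistFit:
    """Marginal log-link Poisson GEE with cluster-robust standard errors.

    ``working_correlation`` is ``"exchangeable"`` (default) or
    ``"independence"``.  The exposure RR is ``exp`` of the exposure
    coefficient; its 95% CI uses the sandwich SE.
    """
    _check_records(records)
    X = build_design(records, covariates)
    cov_struct = {"exchangeable": sm.cov_struct.Exchangeable,
                  "independence": sm.cov_struct.Independence}
    if working_correlation not in cov_struct:
        raise ValueError(
            f"working_correlation must be one of {sorted(cov_struct)}")
    model = sm.GEE(records[OUTCOME_COL].to_numpy(float), X,
                   groups=records["subject_id"].to_numpy(),
                   family=sm.families.Poisson(),
                   cov_struct=cov_struct[working_correlation]())
    res = model.fit()
    params = pd.Series(res.params, index=X.columns)
    if not np.all(np.isfinite(params)) or np.abs(params[EXPOSURE_COL]) > 15:
        raise RuntimeError(
            "GEE fit did not yield a finite exposure coefficient "
            "(possible separation)")
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    beta = float(params[EXPOSURE_COL])
    se = float(np.sqrt(cov.loc[EXPOSURE_COL, EXPOSURE_COL]))
    return FrequentistFit(
        params=params, cov=cov,
        exposure_rr=float(np.exp(beta)), exposure_se=se,
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        n_subjects=int(records["subject_id"].nunique()),
        n_records=int(len(records)),
        model="gee_poisson",
        extra={"working_correlation": working_correlation},
    )


def _re_poisson_negloglik(theta, X, y, cluster_idx, n_clusters, nodes, weights):
    beta, sigma = theta[:-1], theta[-1]
    eta = X @ beta
    # physicists' Gauss-Hermite: integral f(b) phi(b; 0, s^2) db
    #   = pi^{-1/2} sum_k w_k f(sqrt(2) s x_k)
    shifts = np.sqrt(2.0) * sigma * nodes  # (K,)
    per_node = np.zeros((n_clusters, nodes.size))
    base = y * eta - np.exp(eta)
    for k, s in enumerate(shifts):
        ll_rec = y * (eta + s) - np.exp(eta + s) if s != 0.0 else base
        np.add.at(per_node[:, k], cluster_idx, ll_rec)
    cluster_ll = logsumexp(per_node + np.log(weights), axis=1) - 0.5 * np.log(np.pi)
    return -float(cluster_ll.sum())


def fit_re_poisson_ml(records: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                      n_quad: int = 25) -> FrequentistFit:
    """Maximum-likelihood Gaussian random-intercept Poisson fit.

    The per-subject intercept is integrated out by ``n_quad``-point
    Gauss-Hermite quadrature; (beta, sigma) are maximised by L-BFGS-B with
    sigma bounded at zero, so a cohort with no extra-Poisson clustering
    collapses exactly to the ordinary Poisson ML fit.  Returns the
    conditional exposure RR.
    """
    _check_records(records)
    X_df = build_design(records, covariates)
    X = X_df.to_numpy(float)
    y = records[OUTCOME_COL].to_numpy(float)
    codes, _ = pd.factorize(records["subject_id"], sort=False)
    n_clusters = int(codes.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.append(glm.params, 0.3)
    bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
    res = optimize.minimize(
        _re_poisson_negloglik, x0,
        args=(X, y, codes, n_clusters, nodes, weights),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    beta_hat, sigma_hat = res.x[:-1], float(res.x[-1])
    if sigma_hat < 1e-6:
        # boundary solution: the profile likelihood at sigma = 0 is the
        # plain Poisson likelihood, whose exact ML is the IRLS solution
        beta_hat = np.asarray(glm.params, dtype=float)
        sigma_hat = 0.0

    # observed-information covariance for beta (central differences)
    from statsmodels.tools.numdiff import approx_hess

    try:
        H = approx_hess(res.x, _re_poisson_negloglik,
                        args=(X, y, codes, n_clusters, nodes, weights))
        if sigma_hat < 1e-6:  # boundary: drop the sigma row/column
            H = H[:-1, :-1]
            cov_full = np.linalg.inv(H)
        else:
            cov_full = np.linalg.inv(H)[:-1, :-1]
    except np.linalg.LinAlgError:
        cov_full = np.full((X.shape[1], X.shape[1]), np.nan)

    params = pd.Series(beta_hat, index=X_df.columns)
    cov = pd.DataFrame(cov_full, index=X_df.columns, columns=X_df.columns)
    b = float(params[EXPOSURE_COL])
    se = float(np.sqrt(cov.loc[EXPOSURE_COL, EXPOSURE_COL]))
    return FrequentistFit(
        params=params, cov=cov,
        exposure_rr=float(np.exp(b)), exposure_se=se,
        ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
        n_subjects=n_clusters, n_records=int(len(records)),
        model="re_poisson_ml",
        extra={"sigma_re": sigma_hat, "converged": bool(res.success),
               "loglik": -float(res.fun), "optimizer_message": str(res.message)},
    )
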