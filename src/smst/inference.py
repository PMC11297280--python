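"""Fixed-effects probit inference, outlier screening, correlation tests.

The response model regresses each 'old'/'new' recognition decision on
cosine similarity, age group and their interaction through a probit
link, fitted by iteratively reweighted least squares (Fisher scoring
with step-halving, so the log-likelihood never decreases).  Foil trials
are excluded: similarity is undefined without an encoded baseline
phrase, and exact repeats enter at similarity 1.0.

Estimates are also reported exponentiated, matching the reporting scale
of mixed-model analyses of this design (exp(beta) > 1 raises the odds
of an 'old' response, < 1 lowers it).  Random effects for participant,
item and trial order are out of scope here; ``probit_design_matrix``
exposes the exact design so an external mixed-model backend (e.g. lme4
via rpy2) can be plugged in on the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from smst.cohort import TrialResponse, responses_to_frame
from smst.errors import ConvergenceError, DesignError, ValidationError

COEF_NAMES = ("intercept", "sim", "age_old", "sim_x_age_old")


@dataclass
class ProbitFit:
    """Coefficients and uncertainty of the similarity x age probit model."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    exp_estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_obs: int
    converged: bool
    iterations: int
    log_likelihood: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "exp_coef": self.exp_estimates,
                "ci95_lo": {k: v[0] for k, v in self.ci95.items()},
                "ci95_hi": {k: v[1] for k, v in self.ci95.items()},
            }
        )


@dataclass
class OutlierReport:
    """Mahalanobis-distance screen against a chi-square cutoff."""

    excluded_ids: list
    distances: dict
    cutoff: float
    df: int


def probit_design_matrix(
    responses: Sequence[TrialResponse] | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for the similarity x age model on target and lure trials.

    Columns: intercept, similarity, I(old age), similarity * I(old age).
    Foil trials are dropped; targets are coded at similarity 1.0.
    """
    df = responses if isinstance(responses, pd.DataFrame) else responses_to_frame(responses)
    df = df[df.condition != "foil"]
    df = df[df.response.notna()]
    if df.empty:
        raise ValidationError("no target/lure trials in input")
    if df.similarity.isna().any():
        raise ValidationError("target/lure trial with missing similarity")
    groups = set(df.age_group.unique())
    if not {"young", "old"} <= groups:
        raise DesignError(
            f"both age groups required, found {sorted(groups)}"
        )
    sim = df.similarity.to_numpy(dtype=float)
    old = (df.age_group == "old").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), sim, old, sim * old])
    y = (df.response == "old").to_numpy(dtype=float)
    return X, y


def _probit_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # numerically safe log(Phi) via scipy's log-CDF
    return float(np.sum(y * norm.logcdf(eta) + (1 - y) * norm.logcdf(-eta)))


def fit_probit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    ll_trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Maximum-likelihood probit via IRLS (Fisher scoring, step-halved).

    Returns (beta, covariance, iterations, converged, log-likelihood).
    The covariance is the inverse observed information at the optimum.
    Raises :class:`ConvergenceError` on (quasi-)separation, detected as a
    degenerate response vector or a diverging linear predictor.
    """
    n, p = X.shape
    if y.min() == y.max():
        raise ConvergenceError(
            "all responses identical: the likelihood has no finite maximum "
            "(perfect separation)"
        )
    beta = np.zeros(p)
    ll = _probit_loglik(beta, X, y)
    if ll_trace is not None:
        ll_trace.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = norm.cdf(eta)
        phi = norm.pdf(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = phi**2 / (mu * (1 - mu))  # Fisher weights
        z = (y - mu) / np.maximum(phi, 1e-300)
        grad = X.T @ (w * z)
        H = X.T @ (w[:, None] * X)  # expected information
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the log-likelihood non-decreasing
        new_ll = _probit_loglik(beta + step, X, y)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            halvings += 1
            new_ll = _probit_loglik(beta + step, X, y)
        if new_ll < ll:
            break
        beta = beta + step
        if ll_trace is not None:
            ll_trace.append(new_ll)
        if np.max(np.abs(X @ beta)) > 30:
            raise ConvergenceError(
                "linear predictor diverging: data are (quasi-)separated"
            )
        if abs(new_ll - ll) < tol * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # observed information at the optimum
    eta = X @ beta
    mu = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    phi = norm.pdf(eta)
    lam1 = phi / mu  # d/deta log Phi(eta) pieces
    lam0 = phi / (1 - mu)
    w_obs = y * lam1 * (lam1 + eta) + (1 - y) * lam0 * (lam0 - eta)
    H_obs = X.T @ (w_obs[:, None] * X)
    try:
        cov = np.linalg.inv(H_obs)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular observed information: {exc}") from exc
    return beta, cov, it, converged, ll


def fit_probit_similarity_model(
    responses: Sequence[TrialResponse] | pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ProbitFit:
    """Fit the similarity x age probit to target and lure recognition trials."""
    X, y = probit_design_matrix(responses)
    beta, cov, iters, converged, ll = fit_probit(X, y, max_iter=max_iter, tol=tol)
    se = np.sqrt(np.diag(cov))
    zcrit = norm.ppf(0.975)
    return ProbitFit(
        coefficients={k: float(b) for k, b in zip(COEF_NAMES, beta)},
        standard_errors={k: float(s) for k, s in zip(COEF_NAMES, se)},
        exp_estimates={k: float(math.exp(b)) for k, b in zip(COEF_NAMES, beta)},
        ci95={
            k: (float(b - zcrit * s), float(b + zcrit * s))
            for k, b, s in zip(COEF_NAMES, beta, se)
        },
        n_obs=len(y),
        converged=converged,
        iterations=iters,
        log_likelihood=ll,
    )


def mahalanobis_outliers(
    covariates: pd.DataFrame,
    quantile: float = 0.95,
    df: int | None = None,
    id_column: str | None = None,
) -> OutlierReport:
    """Flag rows whose squared Mahalanobis distance exceeds a chi-square cutoff.

    Distances are computed against the sample mean and covariance of the
    covariate columns; the cutoff is the ``quantile`` point of a
    chi-square with ``df`` degrees of freedom (default: the number of
    covariates). ``quantile=1.0`` gives an infinite cutoff (no
    exclusions). When screening a study sample, apply this per age group
    so group mean differences are not mistaken for outliers.
    """
    if id_column is not None:
        ids = covariates[id_column].tolist()
        data = covariates.drop(columns=[id_column])
    else:
        ids = covariates.index.tolist()
        data = covariates
    Xm = data.to_numpy(dtype=float)
    n, p = Xm.shape
    if df is None:
        df = p
    if n < df + 2:
        raise ValidationError(f"need at least df+2={df + 2} rows, got {n}")
    if not (0.0 <= quantile <= 1.0):
        raise ValidationError(f"quantile {quantile} outside [0, 1]")

    mean = Xm.mean(axis=0)
    cov = np.cov(Xm, rowvar=False, ddof=1).reshape(p, p)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular covariance matrix; remove collinear or constant covariates"
        ) from exc
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "near-singular covariance matrix; remove collinear or constant covariates"
        )
    centered = Xm - mean
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    cutoff = float("inf") if quantile >= 1.0 else float(chi2.ppf(quantile, df))
    excluded = [ids[i] for i in range(n) if d2[i] > cutoff]
    return OutlierReport(
        excluded_ids=excluded,
        distances={ids[i]: float(d2[i]) for i in range(n)},
        cutoff=cutoff,
        df=df,
    )


def mahalanobis_outliers_by_group(
    covariates: pd.DataFrame,
    group_column: str,
    quantile: float = 0.95,
    df: int | None = None,
    id_column: str | None = None,
) -> dict[str, OutlierReport]:
    """Run the Mahalanobis screen separately within each group."""
    return {
        str(g): mahalanobis_outliers(
            sub.drop(columns=[group_column]), quantile=quantile, df=df, id_column=id_column
        )
        for g, sub in covariates.groupby(group_column, sort=True)
    }


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    from scipy.stats import pearsonr

    return float(pearsonr(x, y).statistic)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's r-to-z test.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value
    is two-sided from the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValidationError(f"|r| must be < 1, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValidationError(f"need n >= 4 in both samples, got {n}")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0)
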