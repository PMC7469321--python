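"""Gene-level association tests for a panel of correlated CpGs.

Two region-level strategies:

* the **average-methylation** test: the per-sample mean over sites is fed
  to the same per-5% regression models as a single CpG;
* the **weighted truncated product method** (wTPM): the per-CpG p-values
  at or below a truncation threshold tau are combined as a weighted
  product, with weights proportional to the absolute adjusted regression
  coefficients, and calibrated against a permutation null that preserves
  both the covariate structure and the CpG-CpG correlation.

A closed-form null for the *unweighted* truncated product under
independent uniform p-values is provided as an oracle
(:func:`tpm_pvalue_independent`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .association import (
    COVARIATES_BP,
    COVARIATES_HTN,
    logistic_irls,
    ols_fit,
)
from .quant import MethylationMatrix

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.1


@dataclass
class WTPMResult:
    """A combined wTPM statistic with its null calibration metadata."""

    W: float
    tau: float
    weights: np.ndarray
    included: list[str]
    n_included: int
    p_combined: float
    B: int
    null_method: str
    seed: int | None
    outcome: str = ""


def average_methylation(matrix: MethylationMatrix) -> np.ndarray:
    """Per-sample mean methylation over unmasked sites (NaN if all masked)."""
    values = matrix.values
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(values, axis=1)
    n_all_masked = int(np.isnan(values).all(axis=1).sum())
    if n_all_masked:
        logger.warning("%d sample(s) with all sites masked -> missing average",
                       n_all_masked)
    return means


def tpm_statistic(p, tau: float = DEFAULT_TAU) -> float:
    """Truncated product: product of p-values at or below tau (1 if none)."""
    p = np.asarray(p, dtype=float)
    _check_p_tau(p, tau)
    sel = p <= tau
    if not sel.any():
        return 1.0
    return float(np.exp(np.log(p[sel]).sum()))


def wtpm_statistic(p, beta, tau: float = DEFAULT_TAU) -> tuple[float, np.ndarray]:
    """Weighted truncated product with |beta|-proportional exponent weights.

    Over the included set {i : p_i <= tau}, weights are
    ``w_i = |beta_i| / sum |beta_j|`` and ``W = prod p_i ** w_i``.
    Returns (W, weights over the included set, in input order).
    When every included |beta| is zero the weights fall back to equal,
    with a warning.
    """
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if p.shape != beta.shape:
        raise ValueError("p and beta must have the same length")
    _check_p_tau(p, tau)
    sel = p <= tau
    if not sel.any():
        return 1.0, np.array([])
    absb = np.abs(beta[sel])
    total = absb.sum()
    if total == 0.0:
        logger.warning("all included |beta| are zero; falling back to equal weights")
        weights = np.full(sel.sum(), 1.0 / sel.sum())
    else:
        weights = absb / total
    W = float(np.exp(np.sum(weights * np.log(p[sel]))))
    return W, weights


def tpm_pvalue_independent(W: float, L: int, tau: float = DEFAULT_TAU) -> float:
    """P(W* <= W) for the unweighted truncated product of L independent
    Uniform(0,1) p-values truncated at tau (closed form, log-space).

    For each count k of included p-values:
    ``C(L,k) (1-tau)^(L-k) * [ W * sum_{s<k} (k ln tau - ln W)^s / s!``
    when ``W <= tau^k``, else ``tau^k ]``, summed over k = 1..L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if not 0.0 < W <= 1.0:
        raise ValueError("W must lie in (0, 1]")
    if W == 1.0:
        return 1.0
    log_w = math.log(W)
    log_tau = math.log(tau) if tau < 1.0 else 0.0
    log1m_tau = math.log1p(-tau) if tau < 1.0 else -math.inf
    terms = []
    for k in range(1, L + 1):
        log_binom = gammaln(L + 1) - gammaln(k + 1) - gammaln(L - k + 1)
        log_pref = log_binom + (
            (L - k) * log1m_tau if tau < 1.0 else (0.0 if L == k else -math.inf)
        )
        if log_pref == -math.inf:
            continue
        if log_w > k * log_tau:  # W > tau^k
            log_inner = k * log_tau
        else:
            x = k * log_tau - log_w  # >= 0
            s = np.arange(k)
            with np.errstate(divide="ignore"):
                log_terms = s * np.log(x) if x > 0 else np.where(s == 0, 0.0, -np.inf)
            log_inner = log_w + logsumexp(log_terms - gammaln(s + 1))
        terms.append(log_pref + log_inner)
    if not terms:
        return 1.0
    return float(min(1.0, math.exp(logsumexp(terms))))


def _check_p_tau(p: np.ndarray, tau: float) -> None:
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")


# ---------------------------------------------------------------------------
# permutation null


def _batch_ols_last(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For fixed design X (n x p) and many outcomes Y (n x B), return the
    last coefficient's estimate and two-sided t p-value per column."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    C = X.T @ Y  # p x B
    Beta = xtx_inv @ C
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", C, Beta)
    dof = n - p
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = Beta[-1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return Beta[-1], pvals


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after OLS on Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def wtpm_permutation_pvalue(
    methylation: MethylationMatrix,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    tau: float = DEFAULT_TAU,
    B: int = 9999,
    seed: int | None = None,
    weighted: bool = True,
) -> WTPMResult:
    """wTPM with a permutation null honouring covariates and co-methylation.

    Continuous outcomes (``sbp``/``dbp``) use Freedman-Lane: the outcome is
    regressed on covariates alone, and permuted covariate-model residuals
    are added back to the fitted values before the per-CpG statistics are
    recomputed. The binary outcome (``hypertension``) instead permutes the
    covariate-residualized methylation matrix jointly by rows, preserving
    the CpG-CpG correlation. The Monte Carlo p-value uses the add-one rule
    ``(1 + #{W* <= W}) / (B + 1)``.

    With ``weighted=False`` the unweighted truncated product is used
    instead, for comparison against the independent-case closed form.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if covariates is None:
        covariates = COVARIATES_HTN if outcome == "hypertension" else COVARIATES_BP
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        logger.warning("no seed supplied; using generated seed %d", seed)
    rng = np.random.default_rng(seed)

    y = phenotypes[outcome].to_numpy(dtype=float)
    Z = np.column_stack(
        [np.ones(len(y))] + [phenotypes[c].to_numpy(dtype=float) for c in covariates]
    )
    M = methylation.values / 5.0
    ok = np.isfinite(y) & np.isfinite(Z).all(axis=1) & np.isfinite(M).all(axis=1)
    y, Z, M = y[ok], Z[ok], M[ok]
    n, k = M.shape
    labels = methylation.site_labels

    if weighted:
        stat_fn = lambda p, b: wtpm_statistic(p, b, tau)  # noqa: E731
    else:
        stat_fn = lambda p, b: (tpm_statistic(p, tau), np.array([]))  # noqa: E731
    if outcome == "hypertension":
        W_obs, weights, included, n_inc, count = _binary_null(y, Z, M, tau, B, rng, stat_fn)
    else:
        W_obs, weights, included, n_inc, count = _continuous_null(y, Z, M, tau, B, rng, stat_fn)

    p_combined = (1.0 + count) / (B + 1.0)
    return WTPMResult(
        W=W_obs,
        tau=tau,
        weights=weights,
        included=[labels[i] for i in included],
        n_included=n_inc,
        p_combined=float(p_combined),
        B=B,
        null_method="permutation",
        seed=seed,
        outcome=outcome,
    )


def _continuous_null(y, Z, M, tau, B, rng, stat_fn, chunk=512):
    n, k = M.shape
    designs = [np.column_stack([Z, M[:, j]]) for j in range(k)]
    betas = np.empty(k)
    pvals = np.empty(k)
    for j, X in enumerate(designs):
        b, pv = _batch_ols_last(X, y[:, None])
        betas[j], pvals[j] = b[0], pv[0]
    W_obs, weights = stat_fn(pvals, betas)
    included = list(np.flatnonzero(pvals <= tau))

    # covariate-only fit for Freedman-Lane
    gamma, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ gamma
    resid = y - fitted

    count = 0
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = np.array([rng.permutation(n) for _ in range(b)]).T  # n x b
        Ystar = fitted[:, None] + resid[idx]
        p_star = np.empty((k, b))
        b_star = np.empty((k, b))
        for j, X in enumerate(designs):
            bb, pp = _batch_ols_last(X, Ystar)
            b_star[j], p_star[j] = bb, pp
        for c in range(b):
            W_star, _ = stat_fn(p_star[:, c], b_star[:, c])
            if W_star <= W_obs:
                count += 1
        done += b
    return W_obs, weights, included, len(included), count


def _logit_last(Z: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([Z, x])
    beta, se = logistic_irls(X, y)
    z = beta[-1] / se[-1]
    p = 2.0 * stats.norm.sf(abs(z))
    return float(beta[-1]), float(p)


def _binary_null(y, Z, M, tau, B, rng, stat_fn):
    n, k = M.shape
    R = _residualize(M, Z)  # covariate-residualized methylation
    betas = np.empty(k)
    pvals = np.empty(k)
    for j in range(k):
        betas[j], pvals[j] = _logit_last(Z, R[:, j], y)
    W_obs, weights = stat_fn(pvals, betas)
    included = list(np.flatnonzero(pvals <= tau))
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        Rp = R[perm]
        p_star = np.empty(k)
        b_star = np.empty(k)
        for j in range(k):
            b_star[j], p_star[j] = _logit_last(Z, Rp[:, j], y)
        W_star, _ = stat_fn(p_star, b_star)
        if W_star <= W_obs:
            count += 1
    return W_obs, weights, included, len(included), count
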