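"""Single-CpG association models and descriptive comparisons.

Implements the per-5%-methylation linear (SBP/DBP) and logistic
(prevalent hypertension) regressions with the study covariate sets,
phenotype helpers (hypertension classification, mean blood pressure, BMI),
the pooled-variance two-sample t test from summary statistics, and the
Pearson chi-square for 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Covariates adjusted for in the blood-pressure linear models.
COVARIATES_BP = [
    "age",
    "sex",
    "education",
    "current_smoking",
    "current_drinking",
    "bmi",
    "fasting_glucose",
    "ldl_c",
    "hdl_c",
    "antihypertensive_treatment",
]

#: Covariates adjusted for in the hypertension logistic model
#: (the BP set without antihypertensive treatment).
COVARIATES_HTN = COVARIATES_BP[:-1]

COVARIATE_SETS = {"bp": COVARIATES_BP, "htn": COVARIATES_HTN}

_Z975 = 1.959963984540054  # normal 97.5% quantile for Wald intervals


@dataclass(frozen=True)
class SummaryStats:
    """Two-group summary moments (n, mean, SD per group)."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both group sizes must be >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass
class AssocResult:
    """Effect of one CpG (or the region average) on one outcome.

    ``beta_per5`` is the coefficient of methylation/5: mmHg per 5% for
    linear outcomes, log-odds per 5% for the logistic outcome.
    """

    site: str
    outcome: str
    beta_per5: float
    se: float
    p: float
    n_used: int
    or_value: float | None = None
    ci95: tuple[float, float] | None = None
    q: float | None = field(default=None)


def classify_hypertension(sbp, dbp, treated):
    """Hypertension flag: SBP >= 140 or DBP >= 90 or on treatment.

    Accepts scalars or arrays; returns bool or boolean array.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    treated = np.asarray(treated, dtype=bool)
    out = (sbp >= 140.0) | (dbp >= 90.0) | treated
    if out.ndim == 0:
        return bool(out)
    return out


def mean_bp(readings) -> float:
    """Mean of exactly three pressure readings (mmHg)."""
    readings = list(readings)
    if len(readings) != 3:
        raise ValueError(f"expected exactly 3 readings, got {len(readings)}")
    return float(sum(readings)) / 3.0


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index: weight (kg) over squared height (m)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h = height_cm / 100.0
    return weight_kg / (h * h)


def two_sample_t_summary(s: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance Student t test from group moments.

    Returns ``(t, df, two-sided p)`` with ``df = n1 + n2 - 2``.
    """
    df = s.n1 + s.n2 - 2
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / df
    t = (s.mean1 - s.mean2) / math.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df=1, no continuity correction.

    Rows are (a, b) and (c, d); both margins must be positive.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("both margins must be positive")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = stats.chi2.sf(stat, df=1)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# regression internals


def _design(meth: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(meth), meth / 5.0]
    names = ["intercept", "methylation_per5"]
    if covariates is not None:
        for name in covariates.columns:
            cols.append(covariates[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    return X, names


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            mask &= np.isfinite(a)
        else:
            mask &= np.isfinite(a).all(axis=1)
    return mask


def _check_condition(X: np.ndarray, names: list[str]) -> None:
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(
            f"collinear design (condition number {cond:.3g}); columns: {names}"
        )


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients, standard errors, and residual df."""
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, dof


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Converges when the maximum absolute score falls below ``tol``.
    Raises on apparent perfect separation (diverging coefficients).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix in logistic fit") from exc
        # dampen huge Newton steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0:
            raise ValueError("perfect separation detected (diverging coefficient)")
    if np.max(np.abs(beta)) > 30.0:
        raise ValueError("perfect separation detected (diverging coefficient)")
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return beta, se


def fit_linear_bp(
    outcome: np.ndarray,
    methylation: np.ndarray,
    covariates: pd.DataFrame | None = None,
    site: str = "CpG",
    outcome_name: str = "sbp",
) -> AssocResult:
    """Covariate-adjusted OLS of a blood-pressure outcome on methylation/5.

    Complete-case analysis; p-value from the coefficient's t statistic.
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(methylation, dtype=float)
    cov_arr = covariates.to_numpy(dtype=float) if covariates is not None else None
    mask = _complete_cases(y, m, cov_arr)
    n_used = int(mask.sum())
    if n_used < 30:
        raise ValueError(f"fewer than 30 complete cases ({n_used})")
    covs = covariates.loc[mask] if covariates is not None else None
    X, names = _design(m[mask], covs)
    _check_condition(X, names)
    beta, se, dof = ols_fit(X, y[mask])
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), dof)
    return AssocResult(
        site=site,
        outcome=outcome_name,
        beta_per5=float(beta[1]),
        se=float(se[1]),
        p=float(min(p, 1.0)),
        n_used=n_used,
    )


def fit_logistic_htn(
    outcome: np.ndarray,
    methylation: np.ndarray,
    covariates: pd.DataFrame | None = None,
    site: str = "CpG",
    outcome_name: str = "hypertension",
) -> AssocResult:
    """Covariate-adjusted logistic regression of hypertension on methylation/5.

    Reports the odds ratio per 5% methylation with a Wald 95% CI and
    normal-reference p-value.
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(methylation, dtype=float)
    cov_arr = covariates.to_numpy(dtype=float) if covariates is not None else None
    mask = _complete_cases(y, m, cov_arr)
    n_used = int(mask.sum())
    if n_used < 30:
        raise ValueError(f"fewer than 30 complete cases ({n_used})")
    yy = y[mask]
    if len(np.unique(yy)) < 2:
        raise ValueError("outcome has a single class; logistic fit impossible")
    covs = covariates.loc[mask] if covariates is not None else None
    X, names = _design(m[mask], covs)
    _check_condition(X, names)
    beta, se = logistic_irls(X, yy)
    z = beta[1] / se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    lo = math.exp(beta[1] - _Z975 * se[1])
    hi = math.exp(beta[1] + _Z975 * se[1])
    return AssocResult(
        site=site,
        outcome=outcome_name,
        beta_per5=float(beta[1]),
        se=float(se[1]),
        p=float(min(p, 1.0)),
        n_used=n_used,
        or_value=float(math.exp(beta[1])),
        ci95=(float(lo), float(hi)),
    )


def associate_all_sites(
    matrix_values: np.ndarray,
    site_labels: list[str],
    phenotypes: pd.DataFrame,
    outcome: str,
) -> list[AssocResult]:
    """Run the appropriate per-site model for every CpG column.

    ``outcome`` is ``"sbp"``, ``"dbp"`` (linear, BP covariate set) or
    ``"hypertension"`` (logistic, treatment-free covariate set).
    """
    if outcome in ("sbp", "dbp"):
        covs = phenotypes[COVARIATES_BP]
        fit = fit_linear_bp
    elif outcome == "hypertension":
        covs = phenotypes[COVARIATES_HTN]
        fit = fit_logistic_htn
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = phenotypes[outcome].to_numpy(dtype=float)
    results = []
    for j, label in enumerate(site_labels):
        results.append(
            fit(y, matrix_values[:, j], covs, site=label, outcome_name=outcome)
        )
    return results
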