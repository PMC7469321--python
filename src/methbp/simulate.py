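"""Synthetic cohort generation for the methylation-blood-pressure pipeline.

Generates individuals with covariates, correlated CpG methylation (latent
Gaussian copula with moment-matched marginals), systolic/diastolic blood
pressure, hypertension status, antihypertensive treatment, and optionally
per-site bisulfite read counts in the Bismark-coverage dialect.

Two outcome channels are supported:

* **BP channel** (default): SBP/DBP are linear in covariates and
  methylation/5 plus Gaussian noise; hypertension follows the threshold
  rule (SBP >= 140 or DBP >= 90 or treated) with treatment assigned
  Bernoulli among threshold-hypertensives.
* **Logistic channel** (any ``logor_htn_per5`` nonzero): hypertension is
  drawn from a logistic model in covariates and methylation/5 so that a
  covariate-adjusted logistic fit recovers the generating odds ratios;
  blood pressure and treatment are then generated *conditionally* (by
  seeded truncated-normal sampling) so that the threshold classification
  rule reproduces the drawn flags exactly. In this channel the linear BP
  coefficients are distorted by the conditioning and are not recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .association import classify_hypertension
from .quant import CpGSite, MethylationMatrix, nppa_panel

#: Default per-CpG mean methylation (%), on the scale of the bundled
#: reference panel's non-hypertensive group.
DEFAULT_CPG_MEANS = (29.0, 93.3, 23.0, 68.6, 82.0, 40.4, 50.7, 31.1, 36.8)
DEFAULT_CPG_SDS = (5.1, 2.5, 3.8, 6.4, 4.8, 6.1, 6.3, 6.3, 7.6)


@dataclass(frozen=True)
class CovariateParams:
    """Marginal distributions of the simulated covariates."""

    age_mean: float = 52.0
    age_sd: float = 9.5
    male_prob: float = 0.38
    education_prob: float = 0.20
    smoking_prob: float = 0.23
    drinking_prob: float = 0.19
    bmi_mean: float = 24.8
    bmi_sd: float = 3.6
    glucose_mean: float = 5.4
    glucose_sd: float = 1.3
    ldl_mean: float = 3.0
    ldl_sd: float = 0.76
    hdl_mean: float = 1.50
    hdl_sd: float = 0.45


#: covariate -> (effect on SBP, effect on DBP), per unit of the covariate.
DEFAULT_COVARIATE_BP_EFFECTS = {
    "age": (0.5, 0.25),
    "sex": (2.0, 1.0),
    "education": (-1.0, -0.5),
    "current_smoking": (1.0, 0.5),
    "current_drinking": (1.0, 0.5),
    "bmi": (1.0, 0.6),
    "fasting_glucose": (0.8, 0.4),
    "ldl_c": (0.5, 0.3),
    "hdl_c": (-1.0, -0.5),
}


def exponential_decay_corr(n_cpgs: int, rho: float = 0.7) -> np.ndarray:
    """Correlation matrix rho**|i-j| modelling neighbouring co-methylation."""
    idx = np.arange(n_cpgs)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort."""

    n_samples: int = 1000
    seed: int = 0
    cpg_means: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_CPG_MEANS))
    cpg_sds: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_CPG_SDS))
    cpg_corr: np.ndarray | None = None  # defaults to exponential decay, rho=0.7
    beta_sbp_per5: np.ndarray | None = None  # mmHg per 5% methylation
    beta_dbp_per5: np.ndarray | None = None
    logor_htn_per5: np.ndarray | None = None  # log-odds per 5% methylation
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    covariate_bp_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_BP_EFFECTS)
    )
    sbp_intercept: float = 72.0
    dbp_intercept: float = 40.0
    noise_sd_sbp: float = 14.0
    noise_sd_dbp: float = 9.0
    treatment_prob_given_htn: float = 0.5
    htn_prevalence: float = 0.45  # logistic channel only
    htn_covariate_scale: float = 0.05  # log-odds per mmHg of covariate BP effect

    def __post_init__(self) -> None:
        self.cpg_means = np.asarray(self.cpg_means, dtype=float)
        self.cpg_sds = np.asarray(self.cpg_sds, dtype=float)
        k = len(self.cpg_means)
        if self.cpg_corr is None:
            self.cpg_corr = exponential_decay_corr(k)
        self.cpg_corr = np.asarray(self.cpg_corr, dtype=float)
        for name in ("beta_sbp_per5", "beta_dbp_per5", "logor_htn_per5"):
            v = getattr(self, name)
            setattr(self, name, np.zeros(k) if v is None else np.asarray(v, dtype=float))

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_means)

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        k = self.n_cpgs
        if np.any(self.cpg_means < 0) or np.any(self.cpg_means > 100):
            raise ValueError("cpg_means must lie in [0, 100]")
        if np.any(self.cpg_sds <= 0):
            raise ValueError("cpg_sds must be positive")
        if self.cpg_corr.shape != (k, k):
            raise ValueError("cpg_corr shape must match the number of CpGs")
        if not np.allclose(self.cpg_corr, self.cpg_corr.T):
            raise ValueError("cpg_corr must be symmetric")
        if not np.allclose(np.diag(self.cpg_corr), 1.0):
            raise ValueError("cpg_corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.cpg_corr).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"cpg_corr is not positive semidefinite (min eigenvalue {eigmin:.3g})"
            )
        for name in ("beta_sbp_per5", "beta_dbp_per5", "logor_htn_per5"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have length {k}")
        if not 0.0 <= self.treatment_prob_given_htn <= 1.0:
            raise ValueError("treatment_prob_given_htn must lie in [0, 1]")


@dataclass
class Cohort:
    """A generated cohort: phenotypes, methylation, and the generating truth."""

    phenotypes: pd.DataFrame
    methylation: MethylationMatrix
    truth: CohortConfig


@dataclass
class ReadCountModel:
    """Negative-binomial coverage with binomial methylated counts.

    ``conversion_rate`` may be a scalar or one value per sample; the
    unconverted fraction of unmethylated cytosines reads as methylated.
    """

    mean_coverage: float = 1000.0
    coverage_dispersion: float = 10.0
    conversion_rate: float | np.ndarray = 1.0

    def validate(self, n_samples: int) -> np.ndarray:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        rates = np.broadcast_to(
            np.asarray(self.conversion_rate, dtype=float), (n_samples,)
        ).copy()
        if np.any((rates <= 0) | (rates > 1)):
            raise ValueError("conversion_rate must lie in (0, 1]")
        return rates


def _panel_for(k: int) -> list[CpGSite]:
    if k == 9:
        return nppa_panel()
    return [
        CpGSite(chrom="chrS", position=1000 + 10 * j, strand="+",
                tss_offset=10 * j, label=f"CpG{j + 1}")
        for j in range(k)
    ]


def _draw_covariates(cp: CovariateParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(cp.age_mean, cp.age_sd, n),
            "sex": (rng.random(n) < cp.male_prob).astype(int),
            "education": (rng.random(n) < cp.education_prob).astype(int),
            "current_smoking": (rng.random(n) < cp.smoking_prob).astype(int),
            "current_drinking": (rng.random(n) < cp.drinking_prob).astype(int),
            "bmi": rng.normal(cp.bmi_mean, cp.bmi_sd, n),
            "fasting_glucose": rng.normal(cp.glucose_mean, cp.glucose_sd, n),
            "ldl_c": rng.normal(cp.ldl_mean, cp.ldl_sd, n),
            "hdl_c": rng.normal(cp.hdl_mean, cp.hdl_sd, n),
        }
    )


def _truncated_normal(mu, sd, u, lower=None, upper=None):
    """Deterministic truncated-normal draw from uniform ``u`` via the CDF."""
    lo = ndtr((lower - mu) / sd) if lower is not None else 0.0
    hi = ndtr((upper - mu) / sd) if upper is not None else 1.0
    return mu + sd * ndtri(lo + u * (hi - lo))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one reproducible cohort from ``config``.

    See the module docstring for the two outcome channels. The returned
    hypertension flag always equals the threshold classification applied
    to the generated SBP/DBP/treatment columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_cpgs

    # latent Gaussian copula -> moment-matched, clipped methylation
    chol = np.linalg.cholesky(
        config.cpg_corr + 1e-10 * np.eye(k)
    )
    z = rng.standard_normal((n, k)) @ chol.T
    meth = np.clip(config.cpg_means + config.cpg_sds * z, 0.0, 100.0)

    covs = _draw_covariates(config.covariate_params, n, rng)
    eff = config.covariate_bp_effects
    cov_sbp = sum(covs[name].to_numpy() * e[0] for name, e in eff.items())
    cov_dbp = sum(covs[name].to_numpy() * e[1] for name, e in eff.items())
    meth5 = meth / 5.0
    mu_sbp = config.sbp_intercept + cov_sbp + meth5 @ config.beta_sbp_per5
    mu_dbp = config.dbp_intercept + cov_dbp + meth5 @ config.beta_dbp_per5

    logistic_channel = bool(np.any(config.logor_htn_per5 != 0.0))
    if not logistic_channel:
        sbp = mu_sbp + rng.normal(0.0, config.noise_sd_sbp, n)
        dbp = mu_dbp + rng.normal(0.0, config.noise_sd_dbp, n)
        over = (sbp >= 140.0) | (dbp >= 90.0)
        treated = over & (rng.random(n) < config.treatment_prob_given_htn)
    else:
        # hypertension first, from a calibrated logistic model
        eta = meth5 @ config.logor_htn_per5 + config.htn_covariate_scale * cov_sbp
        eta -= eta.mean()
        from scipy.optimize import brentq

        alpha = brentq(
            lambda a: expit(a + eta).mean() - config.htn_prevalence, -50, 50
        )
        htn = rng.random(n) < expit(alpha + eta)
        treated = htn & (rng.random(n) < config.treatment_prob_given_htn)
        # BP consistent with the drawn flags: truncated-normal sampling
        u_s, u_d = rng.random(n), rng.random(n)
        sbp = np.empty(n)
        dbp = np.empty(n)
        free = htn & treated  # treatment alone satisfies the rule
        need_high = htn & ~treated  # must exceed a threshold: force SBP >= 140
        normo = ~htn  # must be below both thresholds
        sbp[free] = mu_sbp[free] + config.noise_sd_sbp * ndtri(u_s[free])
        dbp[free] = mu_dbp[free] + config.noise_sd_dbp * ndtri(u_d[free])
        sbp[need_high] = _truncated_normal(
            mu_sbp[need_high], config.noise_sd_sbp, u_s[need_high], lower=140.0
        )
        dbp[need_high] = mu_dbp[need_high] + config.noise_sd_dbp * ndtri(u_d[need_high])
        sbp[normo] = _truncated_normal(
            mu_sbp[normo], config.noise_sd_sbp, u_s[normo], upper=140.0 - 1e-9
        )
        dbp[normo] = _truncated_normal(
            mu_dbp[normo], config.noise_sd_dbp, u_d[normo], upper=90.0 - 1e-9
        )
        dbp[normo] = np.minimum(dbp[normo], 89.999999)

    dbp = np.minimum(dbp, sbp - 1e-6)  # keep sbp > dbp everywhere
    htn_flag = classify_hypertension(sbp, dbp, treated)

    phenotypes = covs.copy()
    phenotypes.insert(0, "sample_id", [f"S{i + 1:05d}" for i in range(n)])
    phenotypes["sbp"] = sbp
    phenotypes["dbp"] = dbp
    phenotypes["antihypertensive_treatment"] = treated.astype(int)
    phenotypes["hypertension"] = np.asarray(htn_flag).astype(int)

    matrix = MethylationMatrix(
        sample_ids=list(phenotypes["sample_id"]),
        sites=_panel_for(k),
        values=meth,
    )
    return Cohort(phenotypes=phenotypes, methylation=matrix, truth=replace(config))


def generate_read_counts(
    cohort: Cohort, model: ReadCountModel, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Bismark-coverage-dialect records per sample from true methylation.

    Total reads per (sample, site) are negative binomial around
    ``mean_coverage``; methylated counts are binomial with success
    probability ``m + (1 - m)(1 - conversion_rate)`` where ``m`` is the
    true methylation fraction.
    """
    n = len(cohort.methylation.sample_ids)
    rates = model.validate(n)
    rng = np.random.default_rng(cohort.truth.seed + 7919 if seed is None else seed)
    meth = cohort.methylation.values / 100.0
    r = model.coverage_dispersion
    p_nb = r / (r + model.mean_coverage)
    totals = rng.negative_binomial(r, p_nb, size=meth.shape)
    pi = meth + (1.0 - meth) * (1.0 - rates[:, None])
    m_counts = rng.binomial(totals, pi)
    out: dict[str, pd.DataFrame] = {}
    sites = cohort.methylation.sites
    for i, sid in enumerate(cohort.methylation.sample_ids):
        m = m_counts[i]
        u = totals[i] - m
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals[i] > 0, 100.0 * m / np.maximum(totals[i], 1), 0.0)
        out[sid] = pd.DataFrame(
            {
                "chrom": [s.chrom for s in sites],
                "start": [s.position for s in sites],
                "end": [s.position for s in sites],
                "methylation_pct": np.round(pct, 6),
                "count_methylated": m,
                "count_unmethylated": u,
            }
        )
    return out


def write_cohort(
    cohort: Cohort,
    out_dir,
    read_model: ReadCountModel | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write phenotype TSV (and optionally coverage files plus manifest).

    Returns a dict of the written file paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pheno_path = out_dir / "phenotypes.tsv"
    cohort.phenotypes.to_csv(pheno_path, sep="\t", index=False, float_format="%.6g")
    paths["phenotypes"] = str(pheno_path)
    if read_model is not None:
        rates = read_model.validate(len(cohort.methylation.sample_ids))
        counts = generate_read_counts(cohort, read_model, seed=seed)
        cov_dir = out_dir / "coverage"
        cov_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for (sid, frame), rate in zip(counts.items(), rates):
            fpath = cov_dir / f"{sid}.cov"
            frame.to_csv(fpath, sep="\t", index=False, header=False)
            manifest_rows.append((sid, f"coverage/{sid}.cov", rate))
        manifest = pd.DataFrame(
            manifest_rows, columns=["sample_id", "file", "conversion_rate"]
        )
        man_path = out_dir / "manifest.tsv"
        manifest.to_csv(man_path, sep="\t", index=False)
        paths["manifest"] = str(man_path)
    return paths
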