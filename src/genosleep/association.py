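"""Per-SNP covariate-adjusted linear association scans with BH FDR control.

One ordinary-least-squares regression is fitted per variant
(``phenotype ~ intercept + dosage + covariates``); the scan's p-values are
then adjusted by the Benjamini-Hochberg step-up procedure within the scan
(one phenotype x one variant panel forms one FDR family by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genosleep.synthetic_data import GenotypeMatrix

__all__ = [
    "SingularDesignError",
    "fit_linear_model",
    "scan_snps",
    "adjust_fdr",
]

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (or has more columns than rows)."""


def fit_linear_model(
    response: np.ndarray,
    design: np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """OLS coefficient table via QR.

    ``design`` must already contain any intercept column.  Returns a frame
    indexed by coefficient name with columns ``beta``, ``se``, ``t``, ``p``
    (two-sided, t distribution on n-k degrees of freedom).

    Raises :class:`SingularDesignError` on rank deficiency and ValueError
    when n <= k.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(design, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be 2-d")
    n, k = x.shape
    if len(y) != n:
        raise ValueError(f"response has {len(y)} rows but design has {n}")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")

    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if diag.min() <= np.finfo(float).eps * n * max(diag.max(), 1.0):
        raise SingularDesignError("design matrix is rank deficient")

    beta = np.linalg.solve(r, q.T @ y)
    resid = y - x @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)

    if names is None:
        names = [f"x{j}" for j in range(k)]
    return pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p}, index=names)


def adjust_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Rejects the i smallest p-values for the largest i with
    p_(i) <= i*q/m; q-values are the step-up adjusted values
    min_{j>=i} m*p_(j)/j, capped at 1.  Order of the input is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    passes = ranked <= np.arange(1, m + 1) * q / m
    k = np.flatnonzero(passes)
    rejected_sorted = np.zeros(m, dtype=bool)
    if k.size:
        rejected_sorted[: k[-1] + 1] = True
    qvals = np.empty(m)
    rejected = np.empty(m, dtype=bool)
    qvals[order] = qvals_sorted
    rejected[order] = rejected_sorted
    return qvals, rejected


def scan_snps(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    phenotype: str,
    covariates: list[str] | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """One covariate-adjusted regression per SNP, BH-corrected within the scan.

    Monomorphic variants (zero dosage variance among complete cases) are
    flagged and excluded from the FDR family rather than silently dropped.
    Missing data are handled complete-case per regression; drop counts are
    logged.  The ``scaled_estimate`` column is the coefficient with both the
    phenotype and the dosage z-standardized, i.e. beta * SD(dosage)/SD(phenotype).
    """
    covariates = list(covariates or [])
    for col in [phenotype, *covariates]:
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort table")
    if len(cohort) != genotypes.n_individuals:
        raise ValueError("cohort and genotype matrix disagree on individual count")

    pheno_all = cohort[phenotype].to_numpy(dtype=float)
    covar_all = cohort[covariates].to_numpy(dtype=float) if covariates else np.empty((len(cohort), 0))
    k = 2 + len(covariates)

    rows = []
    for j, snp in enumerate(genotypes.snps):
        dosage = genotypes.dosages[:, j].astype(float)
        keep = ~np.isnan(pheno_all)
        if covariates:
            keep &= ~np.isnan(covar_all).any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d incomplete rows", snp.variant_id, n_dropped)
        y = pheno_all[keep]
        g = dosage[keep]
        n_used = len(y)
        if n_used < k + 2:
            raise ValueError(
                f"{snp.variant_id}: only {n_used} complete cases for {k} coefficients"
            )
        base = {
            "variant_id": snp.variant_id,
            "phenotype": phenotype,
            "n_used": n_used,
            "n_dropped": n_dropped,
        }
        if g.std() == 0.0:
            logger.warning("%s: monomorphic among complete cases; excluded from FDR", snp.variant_id)
            rows.append(
                {
                    **base,
                    "beta": math.nan,
                    "se": math.nan,
                    "t_statistic": math.nan,
                    "pval": math.nan,
                    "scaled_estimate": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "monomorphic": True,
                }
            )
            continue
        design = np.column_stack([np.ones(n_used), g, covar_all[keep]])
        coefs = fit_linear_model(y, design, names=["intercept", "dosage", *covariates])
        beta = coefs.loc["dosage", "beta"]
        se = coefs.loc["dosage", "se"]
        tcrit = stats.t.ppf(0.975, df=n_used - k)
        rows.append(
            {
                **base,
                "beta": beta,
                "se": se,
                "t_statistic": coefs.loc["dosage", "t"],
                "pval": coefs.loc["dosage", "p"],
                "scaled_estimate": beta * g.std(ddof=1) / np.std(y, ddof=1),
                "ci_low": beta - tcrit * se,
                "ci_high": beta + tcrit * se,
                "monomorphic": False,
            }
        )

    result = pd.DataFrame(rows)
    result["q_value"] = math.nan
    result["rejected"] = False
    family = ~result["monomorphic"]
    if family.any():
        qvals, rejected = adjust_fdr(result.loc[family, "pval"].to_numpy(), q=fdr_q)
        result.loc[family, "q_value"] = qvals
        result.loc[family, "rejected"] = rejected
    logger.info(
        "scan of %s: m=%d in FDR family, %d rejected at q=%g",
        phenotype,
        int(family.sum()),
        int(result["rejected"].sum()),
        fdr_q,
    )
    return result
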