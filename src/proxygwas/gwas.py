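"""Residualized linear-model association for family-history phenotypes.

The phenotype is the residual from an ordinary least-squares regression of
the observed parental status on covariates (parental age at death/report,
assessment centre, genotype batch, array, principal components); each SNP is
then tested with a simple additive linear model of those residuals on the
offspring dosage. p-values use the normal approximation to the t statistic,
appropriate for the large samples this design targets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import ndtr

from .cohort import TrioCohort, _check_parent

log = logging.getLogger(__name__)


class DegenerateGwasError(ValueError):
    """The analyzed phenotype carries no information (e.g. zero cases)."""


def build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Covariate DataFrame -> design matrix with intercept.

    Numeric columns enter as-is; object/categorical columns are expanded to
    indicator columns dropping the first level.
    """
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names: list[str] = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
            names.append(name)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(float))
                names.append(dname)
    return np.column_stack(cols), names


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def residualize(status: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Least-squares residuals of status on covariates.

    Rows with missing status are dropped from the fit and returned as NaN;
    covariates must be complete for the analyzed rows. A rank-deficient
    design raises an error naming the collinear columns.
    """
    status = np.asarray(status, float)
    mask = ~np.isnan(status)
    if mask.sum() == 0:
        raise DegenerateGwasError("no non-missing status values to residualize")
    design, names = build_design(covariates.iloc[mask].reset_index(drop=True))
    if np.isnan(design).any():
        raise ValueError("covariates contain missing values on analyzed rows")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    y = status[mask]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    out = np.full(status.shape, np.nan)
    out[mask] = y - design @ coef
    return out


def snp_assoc(residuals: np.ndarray, dosage: np.ndarray) -> tuple[float, float, float, float]:
    """Simple least-squares slope of residuals on dosage (with intercept).

    Returns (beta, se, zstat, p) with a two-sided normal p-value.
    """
    residuals = np.asarray(residuals, float)
    dosage = np.asarray(dosage, float)
    if residuals.shape != dosage.shape:
        raise ValueError("residuals and dosage must have the same length")
    mask = ~np.isnan(residuals)
    y = residuals[mask]
    x = dosage[mask]
    n = y.size
    if n < 3:
        raise DegenerateGwasError("need at least 3 observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateGwasError("monomorphic SNP: dosage variance is zero")
    yc = y - y.mean()
    sxy = float(xc @ yc)
    beta = sxy / sxx
    rss = float(yc @ yc) - beta * sxy
    sigma2 = max(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return beta, se, 0.0 if beta == 0 else np.inf, 1.0 if beta == 0 else 0.0
    z = beta / se
    p = float(max(2.0 * ndtr(-abs(z)), np.finfo(float).tiny))
    return float(beta), float(se), float(z), p


def _assoc_table(y: np.ndarray, dosage: np.ndarray, chunk: int = 20_000) -> dict[str, np.ndarray]:
    """Vectorized per-SNP slope/SE/z/p of y on each dosage column."""
    n, m = dosage.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    beta = np.empty(m)
    se = np.empty(m)
    sxx_all = np.empty(m)
    for j0 in range(0, m, chunk):
        x = dosage[:, j0 : j0 + chunk].astype(np.float64)
        sx = x.sum(axis=0)
        sxx = np.einsum("ij,ij->j", x, x) - sx * sx / n
        sxy = yc @ x
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            rss = np.maximum(syy - b * sxy, 0.0)
            s = np.sqrt(rss / (n - 2) / sxx)
        beta[j0 : j0 + chunk] = b
        se[j0 : j0 + chunk] = s
        sxx_all[j0 : j0 + chunk] = sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = np.maximum(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny)
    return {"BETA": beta, "SE": se, "Z": z, "P": p, "SXX": sxx_all}


def _run_gwas(
    cohort: TrioCohort,
    y_raw: np.ndarray,
    covariates: pd.DataFrame,
    maf_min: float,
    info_scores: np.ndarray | None,
    info_min: float,
) -> pd.DataFrame:
    mask = ~np.isnan(y_raw)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateGwasError("no analyzable individuals")
    y_obs = y_raw[mask]
    if np.all(y_obs == y_obs[0]):
        raise DegenerateGwasError("degenerate phenotype: no variation among analyzed rows")
    res = residualize(y_raw, covariates)
    y = res[mask]

    dosage = cohort.offspring_dosage[mask]
    freq = dosage.mean(axis=0, dtype=np.float64) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > maf_min
    if info_scores is not None:
        keep &= np.asarray(info_scores, float) > info_min
    flagged = cohort.variants.loc[maf == 0.0, "SNP"].tolist()
    if flagged:
        log.info("dropping %d monomorphic SNPs", len(flagged))
    keep_idx = np.flatnonzero(keep)

    stats = _assoc_table(y, dosage[:, keep_idx])
    v = cohort.variants.iloc[keep_idx]
    out = pd.DataFrame(
        {
            "SNP": v["SNP"].to_numpy(),
            "CHR": v["CHR"].to_numpy(),
            "BP": v["BP"].to_numpy(),
            "A1": v["A1"].to_numpy(),
            "A2": v["A2"].to_numpy(),
            "FREQ": freq[keep_idx],
            "BETA": stats["BETA"],
            "SE": stats["SE"],
            "Z": stats["Z"],
            "P": stats["P"],
            "N": n,
        }
    )
    out.attrs["n"] = n
    out.attrs["prevalence"] = float(np.mean(y_obs) if np.nanmax(y_obs) <= 1 else np.nan)
    out.attrs["n_snps_dropped"] = int((~keep).sum())
    out.attrs["monomorphic"] = flagged
    return out


def run_proxy_gwas(
    cohort: TrioCohort,
    parent: str,
    maf_min: float = 0.01,
    info_scores: np.ndarray | None = None,
    info_min: float = 0.3,
) -> pd.DataFrame:
    """GWAS of one parent's observed disease status.

    Residualization is fit on that parent's non-missing rows; covariates are
    the parent's age, centre, batch, array and the principal components.
    SNPs with analyzed minor allele frequency <= ``maf_min`` are omitted
    (and those failing the info filter, when scores are supplied). The
    analyzed-sample prevalence is reported in ``.attrs["prevalence"]``.
    """
    _check_parent(parent)
    y = cohort.status(parent)
    if np.nansum(y) == 0:
        raise DegenerateGwasError(f"zero {parent} cases after exclusions")
    age_col = "MATERNAL_AGE" if parent == "maternal" else "PATERNAL_AGE"
    covs = cohort.covariates.copy()
    covs[age_col] = cohort.maternal_age if parent == "maternal" else cohort.paternal_age
    return _run_gwas(cohort, y, covs, maf_min, info_scores, info_min)


def run_combined_gwas(
    cohort: TrioCohort,
    maf_min: float = 0.01,
    info_scores: np.ndarray | None = None,
    info_min: float = 0.3,
    rows: str = "any",
) -> pd.DataFrame:
    """Single GWAS of the number of affected parents (0, 1 or 2).

    With ``rows="any"`` (default) every offspring with at least one
    parent's status observed is analyzed and a missing parent contributes
    no affected count — the reading under which the combined score carries
    the same information as the inverse-variance meta-analysis of the two
    per-parent runs. ``rows="both"`` restricts to offspring with both
    statuses observed. Both parental ages enter as covariates; a missing
    age on an analyzed row is imputed to the analyzed-set mean (its status
    contribution is then zero anyway).
    """
    if rows not in ("any", "both"):
        raise ValueError("rows must be 'any' or 'both'")
    m = cohort.status("maternal")
    p = cohort.status("paternal")
    if rows == "both":
        y = m + p  # NaN wherever either is missing
    else:
        y = np.where(np.isnan(m) & np.isnan(p), np.nan, np.nan_to_num(m) + np.nan_to_num(p))
    if np.all(np.isnan(y)):
        raise DegenerateGwasError("no individuals with an observed parental status")
    if np.nansum(y) == 0:
        raise DegenerateGwasError("degenerate combined phenotype: all parents unaffected")
    covs = cohort.covariates.copy()
    analyzed = ~np.isnan(y)
    for col, age in (("MATERNAL_AGE", cohort.maternal_age), ("PATERNAL_AGE", cohort.paternal_age)):
        age = np.asarray(age, float).copy()
        fill = float(np.nanmean(age[analyzed]))
        age[np.isnan(age)] = fill
        covs[col] = age
    return _run_gwas(cohort, y, covs, maf_min, info_scores, info_min)
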