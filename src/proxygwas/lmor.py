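"""Linear-model coefficient to odds-ratio conversion for proxy GWAS.

A linear regression of a binary trait (prevalence k) on allele dosage with
coefficient beta implies a 2x2 allele-by-disease table with
P(disease | A1 allele) = k + beta (1 - p) and P(disease | A2 allele) =
k - beta p, where p is the A1 allele frequency. The allelic odds ratio is
the cross-product ratio of that table:

    OR = ((k + beta (1 - p)) (1 - k + beta p))
         / ((k - beta p) (1 - k - beta (1 - p)))

Because the phenotype here is a *parent's* status regressed on *offspring*
dosage, the effect is attenuated by the parent-offspring coefficient of
relationship (1/2); the log-odds are therefore doubled to put effects on
the scale of a conventional case-control design. Standard errors of the
scaled log-odds are recovered from the adjusted OR and the (unchanged)
p-value of the linear model, which keeps the z statistic identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

_TERM_NAMES = ("k + beta*(1-p)", "1 - k + beta*p", "k - beta*p", "1 - k - beta*(1-p)")


class LmorDomainError(ValueError):
    """An implied cell probability of the allele-by-disease table is <= 0."""


def _terms(beta, p, k):
    return (
        k + beta * (1.0 - p),
        1.0 - k + beta * p,
        k - beta * p,
        1.0 - k - beta * (1.0 - p),
    )


def lmor(beta: float, p: float, k: float) -> float:
    """Allelic odds ratio implied by a linear-model coefficient.

    Parameters: beta, the linear regression coefficient of the binary trait
    on dosage; p, the effect-allele (A1) frequency in (0,1); k, the trait
    prevalence in (0,1). Raises :class:`LmorDomainError` naming the
    offending term when any implied cell probability is non-positive.
    """
    if not 0.0 < p < 1.0:
        raise LmorDomainError(f"allele frequency p must be in (0,1), got {p}")
    if not 0.0 < k < 1.0:
        raise LmorDomainError(f"prevalence k must be in (0,1), got {k}")
    t = _terms(beta, p, k)
    for value, name in zip(t, _TERM_NAMES):
        if value <= 0.0:
            raise LmorDomainError(
                f"implied probability term ({name}) = {value:.6g} <= 0 "
                f"for beta={beta}, p={p}, k={k}"
            )
    return (t[0] * t[1]) / (t[2] * t[3])


def proxy_scale(or_unscaled: float) -> float:
    """Scaled log-odds 2*ln(OR): the proxy (parent-history) effect doubled
    to the case-control scale. Equivalently the scaled OR is OR**2."""
    or_unscaled = np.asarray(or_unscaled, float)
    if np.any(or_unscaled <= 0.0):
        raise LmorDomainError("odds ratio must be positive")
    out = 2.0 * np.log(or_unscaled)
    return float(out) if out.ndim == 0 else out


def se_from_p(log_or_scaled: float, p_value: float | None = None, fallback_z: float | None = None) -> float:
    """Standard error of the scaled log-odds from the adjusted OR and the
    linear GWAS p-value: SE = |log OR| / z(p).

    When the p-value is degenerate (missing, underflowed to 0, or 1) or the
    log-odds is 0, the linear model's z statistic — identical by
    construction — is used instead.
    """
    z = None
    if p_value is not None and not 0.0 < p_value < 1.0 and fallback_z is None:
        raise ValueError(f"p-value {p_value} outside (0,1) and no fallback z")
    if p_value is not None and 1e-300 < p_value < 1.0:  # quantile unreliable below ~1e-300
        z = float(norm.isf(p_value / 2.0))
        if not np.isfinite(z) or z == 0.0:
            z = None
    if (z is None or log_or_scaled == 0.0) and fallback_z is not None and np.isfinite(fallback_z) and fallback_z != 0.0:
        z = abs(float(fallback_z))
    if z is None or z == 0.0:
        raise ValueError("p-value degenerate and no usable fallback z statistic")
    return abs(log_or_scaled) / z


def transform_table(assoc: pd.DataFrame, k: float, ci: float = 0.95) -> pd.DataFrame:
    """Per-SNP conversion of a linear proxy GWAS table to the case-control scale.

    ``k`` must be the observed prevalence of the analyzed GWAS sample.
    Adds OR (scaled, = unscaled**2), LOG_OR, SE_LOGOR, confidence limits and
    a direction character; rows with a domain failure are flagged in the
    FLAG column with NaN effect estimates rather than aborting the run.
    """
    if not 0.0 < k < 1.0:
        raise LmorDomainError(f"prevalence k must be in (0,1), got {k}")
    beta = assoc["BETA"].to_numpy(float)
    freq = assoc["FREQ"].to_numpy(float)
    z_lin = assoc["Z"].to_numpy(float)
    pval = assoc["P"].to_numpy(float)

    t = _terms(beta, freq, k)
    flag = np.array([""] * len(beta), dtype=object)
    ok = (freq > 0) & (freq < 1)
    flag[~ok] = "freq out of (0,1)"
    for value, name in zip(t, _TERM_NAMES):
        bad = ok & (value <= 0.0)
        flag[bad] = f"({name}) <= 0"
        ok &= value > 0.0

    or_unscaled = np.full(len(beta), np.nan)
    or_unscaled[ok] = (t[0][ok] * t[1][ok]) / (t[2][ok] * t[3][ok])
    log_or = 2.0 * np.log(or_unscaled)

    # z from the p-value (upper-tail quantile at p/2); identical to the
    # linear z by construction, which covers the underflow region
    with np.errstate(all="ignore"):
        z_p = norm.isf(pval / 2.0)
    use_fallback = ~np.isfinite(z_p) | (z_p <= 0.0) | (pval <= 1e-300)
    z_eff = np.where(use_fallback, np.abs(z_lin), z_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(log_or) / z_eff
    se[~ok] = np.nan

    zcrit = float(norm.isf((1.0 - ci) / 2.0))
    out = assoc.copy()
    out["K"] = k
    out["OR_UNSCALED"] = or_unscaled
    out["OR"] = or_unscaled**2
    out["LOG_OR"] = log_or
    out["SE_LOGOR"] = se
    out["L95"] = np.exp(log_or - zcrit * se)
    out["U95"] = np.exp(log_or + zcrit * se)
    out["DIRECTION"] = np.where(np.isnan(log_or), "?", np.where(log_or < 0, "-", "+"))
    out["FLAG"] = flag
    out.attrs = dict(assoc.attrs)
    out.attrs["n_flagged"] = int((~ok).sum())
    return out


def format_or_ci(or_value: float, l95: float, u95: float) -> str:
    """Report-layer formatting of OR and CI to two decimals."""
    return f"{or_value:.2f} ({l95:.2f}, {u95:.2f})"
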