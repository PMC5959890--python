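"""Validity checks for the proxy-phenotype design.

Covers the overlapping-controls sensitivity analysis (combined 0/1/2
parental GWAS versus the meta-analysis of separate maternal and paternal
runs), bulk calibration via the genomic inflation factor, effect-size
concordance between analyses, and recovery of simulation ground truth by
the x2-rescaled odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

# median of a 1-df chi-square: scipy.stats.chi2.ppf(0.5, 1)
CHI2_MEDIAN_1DF = 0.45493642311957283


@dataclass
class DiagnosticsReport:
    p_correlation: float | None = None
    neglog_correlation: float | None = None
    neglog_intercept: float | None = None
    neglog_slope: float | None = None
    lambda_gc: float | None = None
    or_correlation: float | None = None
    sign_concordance: float | None = None
    n_snps: int | None = None
    recovery: pd.DataFrame | None = None
    recovery_summary: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["proxy-GWAS diagnostics", "----------------------"]
        fmt = {
            "p_correlation": "correlation of p-values (raw scale)",
            "neglog_correlation": "correlation of -log10 p",
            "neglog_intercept": "-log10 p regression intercept",
            "neglog_slope": "-log10 p regression slope",
            "lambda_gc": "genomic inflation lambda",
            "or_correlation": "correlation of log-odds ratios",
            "sign_concordance": "sign concordance fraction",
            "n_snps": "shared SNPs",
        }
        for attr, label in fmt.items():
            v = getattr(self, attr)
            if v is not None:
                lines.append(f"{label}: {v:.6g}")
        for key, v in self.recovery_summary.items():
            lines.append(f"recovery {key}: {v:.6g}")
        return "\n".join(lines) + "\n"


def overlap_sensitivity(table_a: pd.DataFrame, table_b: pd.DataFrame) -> DiagnosticsReport:
    """Concordance of two analyses of the same cohort over shared SNPs.

    Reports the Pearson correlation of raw p-values, and the correlation
    plus least-squares intercept/slope of -log10 p of ``table_a`` regressed
    on -log10 p of ``table_b``. Comparing any table with itself returns
    correlation 1, intercept 0, slope 1.
    """
    merged = pd.merge(
        table_a[["SNP", "P"]], table_b[["SNP", "P"]], on="SNP", suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared SNPs, found {len(merged)}")
    pa = merged["P_a"].to_numpy(float)
    pb = merged["P_b"].to_numpy(float)
    la, lb = -np.log10(pa), -np.log10(pb)
    slope, intercept = np.polyfit(lb, la, 1)
    return DiagnosticsReport(
        p_correlation=float(np.corrcoef(pa, pb)[0, 1]),
        neglog_correlation=float(np.corrcoef(la, lb)[0, 1]),
        neglog_intercept=float(intercept),
        neglog_slope=float(slope),
        n_snps=len(merged),
    )


def genomic_inflation(z: np.ndarray | None = None, p: np.ndarray | None = None) -> float:
    """Genomic inflation factor: median association chi-square divided by
    the null 1-df chi-square median (0.454936...)."""
    if z is not None:
        chisq = np.asarray(z, float) ** 2
    elif p is not None:
        chisq = chi2.isf(np.asarray(p, float), 1)
    else:
        raise ValueError("provide z statistics or p-values")
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no finite test statistics")
    if chisq.size < 100:
        warnings.warn("genomic inflation estimated from < 100 tests is unstable")
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def effect_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame, snps=None) -> tuple[float, float]:
    """Pearson correlation of log-odds ratios and the fraction of agreeing
    signs over shared (allele-harmonized) SNPs."""
    from .meta import _effect_se, harmonize_effect

    ea, _ = _effect_se(table_a)
    eb, _ = _effect_se(table_b)
    a = pd.DataFrame(
        {
            "E": ea.to_numpy(float),
            "A1": table_a["A1"].astype(str).to_numpy(),
            "A2": table_a["A2"].astype(str).to_numpy(),
        },
        index=pd.Index(table_a["SNP"]),
    )
    b = pd.DataFrame(
        {
            "E": eb.to_numpy(float),
            "A1": table_b["A1"].astype(str).to_numpy(),
            "A2": table_b["A2"].astype(str).to_numpy(),
        },
        index=pd.Index(table_b["SNP"]),
    )
    shared = a.index.intersection(b.index)
    if snps is not None:
        shared = shared.intersection(pd.Index(snps))
    if len(shared) == 0:
        raise ValueError("no shared SNPs")
    a, b = a.loc[shared], b.loc[shared]
    harmonized = [
        harmonize_effect(e, a1, a2, ra1, ra2)
        for e, a1, a2, ra1, ra2 in zip(b["E"], b["A1"], b["A2"], a["A1"], a["A2"])
    ]
    keep = [i for i, h in enumerate(harmonized) if h is not None]
    if len(keep) < 2:
        raise ValueError("fewer than 2 allele-reconcilable shared SNPs")
    eb_h = np.array([harmonized[i] for i in keep], float)
    ea_v = a["E"].to_numpy(float)[keep]
    mask = np.isfinite(ea_v) & np.isfinite(eb_h)
    r = float(np.corrcoef(ea_v[mask], eb_h[mask])[0, 1])
    conc = float(np.mean(np.sign(ea_v[mask]) == np.sign(eb_h[mask])))
    return r, conc


def recovery_report(
    truth: pd.DataFrame, meta_table: pd.DataFrame, ci_z: float = 1.959963984540054
) -> DiagnosticsReport:
    """Score recovery of the generative per-SNP log-odds by the scaled
    (case-control-scale) meta-analysis estimates.

    ``truth`` needs columns SNP and TRUE_LOG_OR (the per-allele log-odds on
    parental disease). Reports per-SNP estimates with CI coverage plus
    aggregate bias and RMSE over causal and null SNPs separately.
    """
    merged = pd.merge(truth, meta_table[["SNP", "LOG_OR", "SE_LOGOR"]], on="SNP").dropna()
    est = merged["LOG_OR"].to_numpy(float)
    se = merged["SE_LOGOR"].to_numpy(float)
    true = merged["TRUE_LOG_OR"].to_numpy(float)
    covered = np.abs(est - true) <= ci_z * se
    table = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "TRUE_LOG_OR": true,
            "EST_LOG_OR": est,
            "SE_LOGOR": se,
            "CI_COVERS": covered,
        }
    )
    causal = true != 0.0
    summary: dict[str, float] = {}
    for label, mask in (("causal", causal), ("null", ~causal)):
        if mask.any():
            err = est[mask] - true[mask]
            summary[f"{label}_n"] = int(mask.sum())
            summary[f"{label}_bias"] = float(err.mean())
            summary[f"{label}_rmse"] = float(np.sqrt(np.mean(err**2)))
            summary[f"{label}_coverage"] = float(covered[mask].mean())
    return DiagnosticsReport(recovery=table, recovery_summary=summary)


# ----------------------------------------------------------------- plotting


def qq_plot(pvalues, ax=None, path=None):
    """QQ plot of observed vs expected -log10 p under uniformity."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(pvalues, float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, ".", ms=2)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "r-", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def manhattan_plot(stats: pd.DataFrame, ax=None, path=None, sig_threshold: float = 5e-8):
    """Manhattan plot of -log10 p by position."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for _, sub in stats.groupby("CHR", sort=False):
        ax.plot(sub["BP"].to_numpy(float) + offset, -np.log10(sub["P"]), ".", ms=2)
        offset += float(sub["BP"].max())
    ax.axhline(-np.log10(sig_threshold), color="r", lw=1)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def prevalence_from_counts(cases: int, controls: int) -> float:
    """Sample prevalence from case/control counts."""
    if cases < 0 or controls < 0 or cases + controls == 0:
        raise ValueError("counts must be non-negative and not both zero")
    return cases / (cases + controls)
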