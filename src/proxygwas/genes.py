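"""Gene-based association testing with the SNP-wise mean model.

The gene statistic is the mean 1-df chi-square (z^2) over the gene's SNPs.
Its null distribution under LD is that of the mean of squares of a
zero-mean multivariate normal with the SNPs' correlation matrix, estimated
either by Monte Carlo (default) or by a moment-matched scaled-chi-square
(Satterthwaite) approximation. A constant sample size across SNPs is
assumed, so no per-SNP weighting is applied. Family-wise error is
controlled by Bonferroni across genes, and gene-set enrichment uses a
one-sided Fisher exact (hypergeometric) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .loci import LDMatrix

log = logging.getLogger(__name__)


def map_snps_to_genes(variants: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 0) -> dict[str, list[str]]:
    """Assign SNPs to genes whose body (1-based inclusive [START, END]),
    extended by ``window_bp`` on both sides, contains the SNP position."""
    required = {"GENE", "CHR", "START", "END"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene annotation must have columns {sorted(required)}")
    bad = genes["START"] > genes["END"]
    if bad.any():
        raise ValueError(f"degenerate gene intervals (start > end): {genes.loc[bad, 'GENE'].tolist()}")
    mapping: dict[str, list[str]] = {}
    bp = variants["BP"].to_numpy()
    chrom = variants["CHR"].to_numpy(str)
    snps = variants["SNP"].to_numpy()
    for _, g in genes.iterrows():
        mask = (chrom == str(g["CHR"])) & (bp >= g["START"] - window_bp) & (bp <= g["END"] + window_bp)
        hit = snps[mask].tolist()
        if hit:
            mapping[g["GENE"]] = hit
    return mapping


@dataclass
class GeneResult:
    gene: str
    n_snps: int
    stat: float  # mean of SNP chi-squares
    p_gene: float
    method: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


def _repair_correlation(r: np.ndarray, tol: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose and clip negative eigenvalues at 0. Raises when the
    matrix is non-PSD beyond repair tolerance (most-negative eigenvalue
    below -tol relative to the largest)."""
    r = np.asarray(r, float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(r)
    if w.min() < -tol * max(w.max(), 1.0):
        raise ValueError(f"correlation matrix non-PSD beyond repair (min eigenvalue {w.min():.4g})")
    w = np.clip(w, 0.0, None)
    return w, v


def gene_test(
    zstats: np.ndarray,
    r: np.ndarray,
    n_draws: int = 1_000_000,
    seed: int = 0,
    method: str = "monte_carlo",
    gene: str = "",
) -> GeneResult:
    """SNP-wise mean test for one gene.

    ``zstats`` are the gene's SNP z statistics, ``r`` their signed LD
    correlation matrix from the reference panel. The statistic is
    mean(z^2); ``method="monte_carlo"`` estimates its tail by drawing from
    N(0, r) (p = (count + 1)/(n_draws + 1)); ``method="satterthwaite"``
    moment-matches a scaled chi-square (exact when r is the identity).
    """
    z = np.atleast_1d(np.asarray(zstats, float))
    m = z.size
    if m == 0:
        raise ValueError("gene has no SNPs")
    r = np.atleast_2d(np.asarray(r, float))
    if r.shape != (m, m):
        raise ValueError(f"correlation matrix shape {r.shape} does not match {m} SNPs")
    stat = float(np.mean(z**2))
    w, v = _repair_correlation(r)

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        a = v * np.sqrt(w)  # draws = N(0, I) @ a.T have covariance r
        count = 0
        chunk = max(1, min(200_000, n_draws))
        done = 0
        while done < n_draws:
            k = min(chunk, n_draws - done)
            g = rng.standard_normal((k, m)) @ a.T
            count += int(np.count_nonzero((g**2).mean(axis=1) >= stat))
            done += k
        p = (count + 1.0) / (n_draws + 1.0)
    elif method == "satterthwaite":
        # mean(T) = 1, var(T) = 2 sum(r_ij^2) / m^2 ; T ~ (V/2) chi2_{2/V}
        r_rep = (v * w) @ v.T
        variance = 2.0 * float(np.sum(r_rep**2)) / m**2
        if variance <= 0:
            raise ValueError("degenerate null variance")
        scale = variance / 2.0
        df = 2.0 / variance
        p = float(chi2.sf(stat / scale, df))
        p = max(p, np.finfo(float).tiny)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GeneResult(gene=gene, n_snps=m, stat=stat, p_gene=float(p), method=method)


def gene_analysis(
    stats: pd.DataFrame,
    ld: LDMatrix,
    genes: pd.DataFrame,
    window_bp: int = 0,
    method: str = "monte_carlo",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the SNP-wise mean test for every annotated gene with mapped SNPs.

    ``stats`` must carry Z statistics; LD comes from the same reference
    panel used for locus definition. Returns one row per tested gene.
    """
    variants = stats[["SNP", "CHR", "BP"]]
    mapping = map_snps_to_genes(variants, genes, window_bp=window_bp)
    zmap = dict(zip(stats["SNP"], stats["Z"].astype(float)))
    rows = []
    ginfo = genes.set_index("GENE")
    for i, (gene, snps) in enumerate(sorted(mapping.items())):
        usable = [s for s in snps if s in zmap and s not in ld.monomorphic]
        if not usable:
            continue
        z = np.array([zmap[s] for s in usable])
        r = ld.submatrix(usable)
        res = gene_test(z, r, n_draws=n_draws, seed=seed + i, method=method, gene=gene)
        rows.append(
            {
                "GENE": gene,
                "CHR": str(ginfo.loc[gene, "CHR"]),
                "START": int(ginfo.loc[gene, "START"]),
                "END": int(ginfo.loc[gene, "END"]),
                "NSNPS": res.n_snps,
                "STAT": res.stat,
                "P": res.p_gene,
                "METHOD": res.method,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(n_genes: int) -> float:
    """Family-wise 5% significance threshold: 0.05 / number of tests."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return 0.05 / n_genes


def fisher_gene_set(
    significant_genes, gene_sets: dict[str, list], universe
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per gene set.

    For each set, the 2x2 table (in set x significant) over the gene
    universe gives a hypergeometric tail p; fold is observed/expected
    significant members. Sets must be subsets of the universe.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("gene universe is empty")
    uset = set(universe)
    sig = set(significant_genes) & uset
    n_universe, n_sig = len(uset), len(sig)
    rows = []
    for name, members in gene_sets.items():
        mset = set(members)
        if not mset <= uset:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
        n_set = len(mset)
        n_hit = len(mset & sig)
        expected = n_set * n_sig / n_universe
        p = float(hypergeom.sf(n_hit - 1, n_universe, n_sig, n_set))
        rows.append(
            {
                "SET": name,
                "N_SET": n_set,
                "N_SIGNIFICANT": n_hit,
                "EXPECTED": expected,
                "FOLD": n_hit / expected if expected > 0 else np.nan,
                "P": p,
            }
        )
    return pd.DataFrame(rows)
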