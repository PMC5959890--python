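"""Synthetic trio cohorts for proxy-phenotype (family-history) GWAS.

Offspring are genotyped; their parents are not. Parental genotypes are drawn
under Hardy-Weinberg equilibrium at each SNP's allele frequency, the offspring
receives one allele from each parent under Mendelian transmission, and
parental disease is generated from the *parent's own* genotype through a
logistic model whose intercept is calibrated so the population prevalence
matches the configured value. The offspring then "reports" each parent's
status with imperfect sensitivity/specificity, and statuses are masked
(set missing) when a parent is under 60, died before 60, or has no age
information — the exclusion rules a family-history questionnaire study
applies.

Ground truth (latent parental genotypes, per-SNP causal log-odds, calibrated
intercepts) is retained so downstream parameter-recovery can be scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

from .config import ConfigError, SimulationConfig

log = logging.getLogger(__name__)

PARENTS = ("maternal", "paternal")

# non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


class CalibrationError(RuntimeError):
    """Prevalence calibration could not bracket the target."""


@dataclass
class TrioCohort:
    """A simulated cohort of genotyped offspring with latent parents.

    Dosages count copies of A1 (the effect allele). ``*_status`` holds the
    observed (reported, exclusion-masked) parental status as float with NaN
    for missing; ``*_true`` holds the latent disease indicator.
    """

    config: SimulationConfig
    variants: pd.DataFrame  # SNP, CHR, BP, A1, A2, MAF
    offspring_dosage: np.ndarray  # (n, m) int8
    maternal_genotype: np.ndarray | None
    paternal_genotype: np.ndarray | None
    truth_log_or: np.ndarray  # (m,) per-allele log-odds on parental disease
    causal_idx: np.ndarray
    seed: int
    maternal_true: np.ndarray | None = None
    paternal_true: np.ndarray | None = None
    maternal_status: np.ndarray | None = None
    paternal_status: np.ndarray | None = None
    maternal_age: np.ndarray | None = None
    paternal_age: np.ndarray | None = None
    maternal_died60: np.ndarray | None = None
    paternal_died60: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    alpha: dict = field(default_factory=dict)  # calibrated logistic intercepts
    exclusions: dict = field(default_factory=dict)

    @property
    def n_offspring(self) -> int:
        return self.offspring_dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.offspring_dosage.shape[1]

    def parent_genotype(self, parent: str) -> np.ndarray:
        _check_parent(parent)
        g = self.maternal_genotype if parent == "maternal" else self.paternal_genotype
        if g is None:
            raise ValueError(f"{parent} genotypes are not available on this cohort")
        return g

    def status(self, parent: str) -> np.ndarray:
        _check_parent(parent)
        s = self.maternal_status if parent == "maternal" else self.paternal_status
        if s is None:
            raise ValueError(f"{parent} observed status not simulated yet")
        return s

    def prevalence(self, parent: str) -> float:
        """Observed prevalence among non-missing reports for one parent."""
        s = self.status(parent)
        return float(np.nanmean(s))

    # ---------------------------------------------------------------- IO
    def save(self, outdir) -> None:
        """Write the cohort as plain TSV files plus a YAML sidecar.

        Latent parental genotypes are not written (they are simulation
        internals); everything the analysis pipeline consumes is.
        """
        from . import io as pio  # local import to avoid a cycle

        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_dosage_matrix(self.offspring_dosage, self.variants, outdir)
        pheno = pd.DataFrame(
            {
                "IID": np.arange(self.n_offspring),
                "MATERNAL_STATUS": self.maternal_status,
                "PATERNAL_STATUS": self.paternal_status,
                "MATERNAL_AGE": self.maternal_age,
                "PATERNAL_AGE": self.paternal_age,
            }
        )
        pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False, na_rep="NA")
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            {
                "SNP": self.variants["SNP"],
                "TRUE_LOG_OR": self.truth_log_or,
                "CAUSAL": np.isin(np.arange(self.n_snps), self.causal_idx).astype(int),
            }
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        meta = {
            "seed": int(self.seed),
            "alpha": {k: float(v) for k, v in self.alpha.items()},
            "exclusions": {k: {kk: int(vv) for kk, vv in v.items()} for k, v in self.exclusions.items()},
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
        }
        with open(outdir / "cohort.yml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def load(cls, indir) -> "TrioCohort":
        from . import io as pio

        import pathlib

        indir = pathlib.Path(indir)
        dosage, variants = pio.read_dosage_matrix(indir)
        with open(indir / "cohort.yml") as fh:
            meta = yaml.safe_load(fh)
        config = SimulationConfig.from_dict(meta["config"])
        pheno = pd.read_csv(indir / "phenotypes.tsv", sep="\t", na_values="NA")
        covs = pd.read_csv(indir / "covariates.tsv", sep="\t")
        for c in ("CENTRE", "BATCH", "ARRAY"):
            if c in covs:
                covs[c] = covs[c].astype(str)
        truth = pd.read_csv(indir / "truth.tsv", sep="\t")
        return cls(
            config=config,
            variants=variants,
            offspring_dosage=dosage,
            maternal_genotype=None,
            paternal_genotype=None,
            truth_log_or=truth["TRUE_LOG_OR"].to_numpy(float),
            causal_idx=np.flatnonzero(truth["CAUSAL"].to_numpy(int)),
            seed=int(meta["seed"]),
            maternal_status=pheno["MATERNAL_STATUS"].to_numpy(float),
            paternal_status=pheno["PATERNAL_STATUS"].to_numpy(float),
            maternal_age=pheno["MATERNAL_AGE"].to_numpy(float),
            paternal_age=pheno["PATERNAL_AGE"].to_numpy(float),
            covariates=covs,
            alpha=dict(meta.get("alpha", {})),
            exclusions=dict(meta.get("exclusions", {})),
        )


def _check_parent(parent: str) -> None:
    if parent not in PARENTS:
        raise ValueError(f"parent must be one of {PARENTS}, got {parent!r}")


# ------------------------------------------------------------------ genotypes


def _draw_haplotypes(rng: np.random.Generator, n: int, maf: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """One haplotype per row: Bernoulli(maf) alleles, optionally correlated
    within blocks through an AR(1) Gaussian copula (marginals preserved)."""
    m = maf.size
    if config.ld_block_size <= 1 or config.ld_rho == 0.0:
        return (rng.random((n, m)) < maf).astype(np.int8)
    z = rng.standard_normal((n, m))
    rho = config.ld_rho
    scale = np.sqrt(1.0 - rho * rho)
    bs = config.ld_block_size
    for j in range(1, m):
        if j % bs != 0:  # correlate within a block only
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return (z < ndtri(maf)).astype(np.int8)


def _transmit(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray, block_size: int) -> np.ndarray:
    """Pick one of the parent's two haplotypes per block (free recombination
    between blocks, none within; block size 1 = independent SNPs)."""
    n, m = hap_a.shape
    n_blocks = -(-m // block_size)
    pick = rng.integers(0, 2, size=(n, n_blocks)).astype(bool)
    pick = np.repeat(pick, block_size, axis=1)[:, :m]
    return np.where(pick, hap_a, hap_b)


def simulate_trio_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> TrioCohort:
    """Draw parental genotypes (HWE at each SNP's MAF) and offspring dosages
    by Mendelian transmission. Returns a cohort with genotypes only."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_offspring, config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    mat_h1 = _draw_haplotypes(rng, n, maf, config)
    mat_h2 = _draw_haplotypes(rng, n, maf, config)
    pat_h1 = _draw_haplotypes(rng, n, maf, config)
    pat_h2 = _draw_haplotypes(rng, n, maf, config)
    maternal = mat_h1 + mat_h2
    paternal = pat_h1 + pat_h2
    child = (
        _transmit(rng, mat_h1, mat_h2, config.ld_block_size)
        + _transmit(rng, pat_h1, pat_h2, config.ld_block_size)
    ).astype(np.int8)

    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pairs])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pairs])
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{100000 + j}" for j in range(m)],
            "CHR": "1",
            "BP": 1 + config.bp_spacing * np.arange(m),  # 1-based
            "A1": a1,
            "A2": a2,
            "MAF": maf,
        }
    )

    if config.n_causal > 0:
        causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    else:
        causal_idx = np.empty(0, dtype=int)
    truth = np.zeros(m)
    truth[causal_idx] = np.asarray(config.causal_log_or, float)

    return TrioCohort(
        config=config,
        variants=variants,
        offspring_dosage=child,
        maternal_genotype=maternal,
        paternal_genotype=paternal,
        truth_log_or=truth,
        causal_idx=causal_idx,
        seed=config.seed,
    )


# ------------------------------------------------------------------- disease


def calibrate_intercept(score: np.ndarray, k: float, tol: float = 1e-9) -> float:
    """Intercept alpha with mean(expit(alpha + score)) == k, by root bracketing.

    The calibration targets the population-average risk over the simulated
    genotype distribution; tolerance on the achieved prevalence is < 1e-6.
    """
    smin = float(np.min(score)) if np.size(score) else 0.0
    smax = float(np.max(score)) if np.size(score) else 0.0
    lo, hi = -45.0 - smax, 45.0 - smin  # bracket adapts to the score range

    def f(a: float) -> float:
        return float(np.mean(expit(a + score)) - k)

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"cannot bracket prevalence k={k}: risk range "
            f"[{flo + k:.3g}, {fhi + k:.3g}] over alpha in [{lo}, {hi}]"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def simulate_parent_disease(
    cohort: TrioCohort,
    config: SimulationConfig,
    parent: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent disease indicator for one parent: logistic in the parent's own
    genotype at the causal SNPs, prevalence-calibrated intercept."""
    _check_parent(parent)
    if rng is None:
        rng = np.random.default_rng(config.seed + (1 if parent == "maternal" else 2))
    g = cohort.parent_genotype(parent)
    k = config.k_maternal if parent == "maternal" else config.k_paternal
    beta = cohort.truth_log_or[cohort.causal_idx]
    score = g[:, cohort.causal_idx].astype(np.float64) @ beta if beta.size else np.zeros(cohort.n_offspring)
    alpha = calibrate_intercept(score, k)
    prob = expit(alpha + score)
    status = (rng.random(cohort.n_offspring) < prob).astype(np.int8)
    cohort.alpha[parent] = alpha
    if parent == "maternal":
        cohort.maternal_true = status
    else:
        cohort.paternal_true = status
    return status


# ------------------------------------------------- ages, covariates, reports


def simulate_ages_and_covariates(
    cohort: TrioCohort, config: SimulationConfig, rng: np.random.Generator | None = None
) -> None:
    """Parental ages (at death or at the offspring's report) and the
    offspring-level covariate table (centre, batch, array, PCs)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = cohort.n_offspring
    for parent in PARENTS:
        age = rng.normal(config.parent_age_mean, config.parent_age_sd, size=n)
        died60 = rng.random(n) < config.p_death_before_60
        age = np.where(died60, rng.uniform(45.0, 60.0, size=n), age)
        age[rng.random(n) < config.p_missing_age] = np.nan
        if parent == "maternal":
            cohort.maternal_age, cohort.maternal_died60 = age, died60
        else:
            cohort.paternal_age, cohort.paternal_died60 = age, died60
    covs = pd.DataFrame(
        {
            "CENTRE": rng.integers(0, config.n_centres, size=n).astype(str),
            "BATCH": rng.integers(0, config.n_batches, size=n).astype(str),
            "ARRAY": rng.integers(0, config.n_arrays, size=n).astype(str),
        }
    )
    for j in range(config.n_pcs):
        covs[f"PC{j + 1}"] = rng.standard_normal(n)
    cohort.covariates = covs


def apply_reporting_and_exclusions(
    cohort: TrioCohort, config: SimulationConfig, rng: np.random.Generator | None = None
) -> None:
    """Observed statuses: misreport per sensitivity/specificity, then mask
    parents aged under 60, dead before 60, or without age information."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    sens, spec = config.report_sensitivity, config.report_specificity
    eta = 0.0
    if config.covariate_report_effect != 0.0 and cohort.covariates is not None:
        # ascertainment artifact: reporting probability shifts with PC1
        eta = config.covariate_report_effect * cohort.covariates["PC1"].to_numpy()
    for parent in PARENTS:
        true = cohort.maternal_true if parent == "maternal" else cohort.paternal_true
        if true is None:
            raise ValueError(f"simulate_parent_disease must run before reporting ({parent})")
        p_report = np.where(
            true == 1,
            expit(logit(np.clip(sens, 1e-12, 1 - 1e-12)) + eta),
            expit(logit(np.clip(1 - spec, 1e-12, 1 - 1e-12)) + eta),
        )
        if sens == 1.0:
            p_report = np.where(true == 1, 1.0, p_report)
        if spec == 1.0:
            p_report = np.where(true == 0, 0.0, p_report)
        observed = (rng.random(cohort.n_offspring) < p_report).astype(float)

        age = cohort.maternal_age if parent == "maternal" else cohort.paternal_age
        died60 = cohort.maternal_died60 if parent == "maternal" else cohort.paternal_died60
        missing_age = np.isnan(age)
        under60 = (~missing_age) & (age < 60.0) & (~died60)
        excluded = missing_age | died60 | under60
        observed[excluded] = np.nan
        counts = {
            "age_under_60": int(under60.sum()),
            "died_before_60": int(died60.sum()),
            "age_missing": int(missing_age.sum()),
            "excluded_total": int(excluded.sum()),
            "analyzed": int((~excluded).sum()),
        }
        cohort.exclusions[parent] = counts
        if counts["analyzed"] == 0:
            warnings.warn(f"all {parent} statuses excluded under this configuration")
        log.info("%s reporting: %s", parent, counts)
        if parent == "maternal":
            cohort.maternal_status = observed
        else:
            cohort.paternal_status = observed


def simulate_cohort(config: SimulationConfig) -> TrioCohort:
    """Full generative pass: genotypes, disease, ages/covariates, reporting.

    All randomness flows from a single generator seeded with ``config.seed``;
    re-running with the same configuration is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_trio_genotypes(config, rng)
    simulate_parent_disease(cohort, config, "maternal", rng)
    simulate_parent_disease(cohort, config, "paternal", rng)
    simulate_ages_and_covariates(cohort, config, rng)
    apply_reporting_and_exclusions(cohort, config, rng)
    log.info("simulated cohort: n=%d, m=%d, seed=%d, config=%s",
             cohort.n_offspring, cohort.n_snps, config.seed, config.config_hash())
    return cohort


# -------------------------------------------------------------------- oracle


def _score_distribution(maf: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of sum(beta_l * G_l) over independent HWE genotypes."""
    vals = np.array([0.0])
    probs = np.array([1.0])
    for p, b in zip(maf, beta):
        gp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        vals = (vals[:, None] + b * np.arange(3)[None, :]).ravel()
        probs = (probs[:, None] * gp[None, :]).ravel()
    return vals, probs


def true_allele_risks(
    cohort: TrioCohort, snp_index: int, parent: str = "maternal", n_pop: int = 200_000, seed: int = 12345
) -> tuple[float, float]:
    """Exact marginal disease risks P(disease | allele) for the two alleles
    (A2-carrying, A1-carrying) at one SNP, integrating the logistic risk
    over the HWE distribution of the causal background."""
    _check_parent(parent)
    if not 0 <= snp_index < cohort.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range [0, {cohort.n_snps})")
    if parent not in cohort.alpha:
        raise ValueError("simulate_parent_disease must run before computing risks")
    maf = float(cohort.variants["MAF"].iloc[snp_index])
    alpha = cohort.alpha[parent]
    beta_j = float(cohort.truth_log_or[snp_index])
    others = cohort.causal_idx[cohort.causal_idx != snp_index]
    maf_o = cohort.variants["MAF"].to_numpy(float)[others]
    beta_o = cohort.truth_log_or[others]
    if others.size <= 13:
        s_vals, s_probs = _score_distribution(maf_o, beta_o)
    else:
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, maf_o, size=(n_pop, maf_o.size))
        s_vals = g @ beta_o
        s_probs = np.full(n_pop, 1.0 / n_pop)
    risks = []
    for a in (0, 1):
        risk = 0.0
        for b, pb in ((0, 1 - maf), (1, maf)):
            risk += pb * float(np.sum(s_probs * expit(alpha + beta_j * (a + b) + s_vals)))
        risks.append(risk)
    return risks[0], risks[1]


def true_allelic_or(
    cohort: TrioCohort,
    snp_index: int,
    parent: str = "maternal",
    method: str = "exact",
    n_pop: int = 200_000,
    seed: int = 12345,
) -> float:
    """Ground-truth allele-level odds ratio of parental disease at one SNP.

    ``method="tabulate"`` draws a fresh parent population from the generative
    model and cross-tabulates alleles against realized disease;
    ``method="exact"`` integrates the logistic risk over the HWE genotype
    distribution of the causal set (noise-free up to the stored MAFs).
    Monomorphic SNPs are undefined and return NaN with a warning.
    """
    _check_parent(parent)
    if not 0 <= snp_index < cohort.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range [0, {cohort.n_snps})")
    if parent not in cohort.alpha:
        raise ValueError("simulate_parent_disease must run before true_allelic_or")
    maf = float(cohort.variants["MAF"].iloc[snp_index])
    if maf <= 0.0 or maf >= 1.0:
        warnings.warn(f"SNP index {snp_index} is monomorphic; allelic OR undefined")
        return float("nan")
    alpha = cohort.alpha[parent]
    beta_j = float(cohort.truth_log_or[snp_index])
    others = cohort.causal_idx[cohort.causal_idx != snp_index]
    maf_o = cohort.variants["MAF"].to_numpy(float)[others]
    beta_o = cohort.truth_log_or[others]

    if method == "exact":
        p0, p1 = true_allele_risks(cohort, snp_index, parent, n_pop=n_pop, seed=seed)
        return (p1 / (1 - p1)) / (p0 / (1 - p0))

    if method == "tabulate":
        rng = np.random.default_rng(seed)
        g_j = rng.binomial(2, maf, size=n_pop).astype(np.float64)
        score = beta_j * g_j
        if others.size:
            g_o = rng.binomial(2, maf_o, size=(n_pop, maf_o.size))
            score = score + g_o @ beta_o
        disease = rng.random(n_pop) < expit(alpha + score)
        n11 = float(g_j[disease].sum())  # case alleles A1
        n01 = float((2 - g_j[disease]).sum())
        n10 = float(g_j[~disease].sum())
        n00 = float((2 - g_j[~disease]).sum())
        if min(n11, n01, n10, n00) == 0:
            warnings.warn("empty cell in allele-by-disease table; OR undefined")
            return float("nan")
        return (n11 * n00) / (n01 * n10)

    raise ValueError(f"unknown method {method!r}")


def simulate_reference_panel(
    config: SimulationConfig, n_individuals: int, variants: pd.DataFrame | None = None, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Unrelated diploid genotype panel from the same haplotype model, for
    use as an LD reference (locus definition, gene-based null)."""
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    if variants is None:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=config.n_snps)
        variants = pd.DataFrame(
            {
                "SNP": [f"rs{100000 + j}" for j in range(config.n_snps)],
                "CHR": "1",
                "BP": 1 + config.bp_spacing * np.arange(config.n_snps),
                "A1": "A",
                "A2": "G",
                "MAF": maf,
            }
        )
    maf = variants["MAF"].to_numpy(float)
    dosage = _draw_haplotypes(rng, n_individuals, maf, config) + _draw_haplotypes(
        rng, n_individuals, maf, config
    )
    return dosage.astype(np.int8), variants
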