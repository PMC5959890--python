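"""Generative-model tests: Mendelian transmission, prevalence calibration,
reporting/exclusion bookkeeping and the ground-truth odds-ratio oracle."""

import numpy as np
import pytest

import proxygwas as pg
from proxygwas.config import ConfigError


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        pg.SimulationConfig(maf_range=(0.005, 0.5))
    with pytest.raises(ConfigError):
        pg.SimulationConfig(n_snps=10, n_causal=11)
    with pytest.raises(ConfigError):
        pg.SimulationConfig(k_maternal=0.05, k_paternal=0.09)  # paternal > maternal
    with pytest.raises(ConfigError):
        pg.SimulationConfig(report_sensitivity=1.2)


def test_mendelian_transmission_bounds():
    """Each offspring allele comes from the matching parent: dosage is
    bounded by the parents' homozygosity, and two hom-ref parents force 0."""
    cfg = pg.SimulationConfig(n_offspring=2_000, n_snps=50, n_causal=0, seed=5)
    c = pg.simulate_trio_genotypes(cfg)
    lower = (c.maternal_genotype == 2).astype(int) + (c.paternal_genotype == 2).astype(int)
    upper = (c.maternal_genotype > 0).astype(int) + (c.paternal_genotype > 0).astype(int)
    assert np.all(c.offspring_dosage >= lower)
    assert np.all(c.offspring_dosage <= upper)
    both_ref = (c.maternal_genotype == 0) & (c.paternal_genotype == 0)
    assert np.all(c.offspring_dosage[both_ref] == 0)


def test_parent_offspring_dosage_correlation_half():
    """Mendelian transmission implies corr(offspring, one parent) = 1/2."""
    cfg = pg.SimulationConfig(
        n_offspring=50_000, n_snps=5, n_causal=0, maf_range=(0.49, 0.5), seed=6
    )
    c = pg.simulate_trio_genotypes(cfg)
    for j in range(c.n_snps):
        r = np.corrcoef(c.offspring_dosage[:, j], c.maternal_genotype[:, j])[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)


def test_parent_offspring_correlation_tolerance_scales_with_n(mid_cohort):
    """Per-SNP correlation within 3/sqrt(n) of 1/2 across a whole cohort."""
    c = mid_cohort
    tol = 3.0 / np.sqrt(c.n_offspring)
    x = c.offspring_dosage.astype(float)
    for parent_g in (c.maternal_genotype, c.paternal_genotype):
        g = parent_g.astype(float)
        xc = x - x.mean(0)
        gc = g - g.mean(0)
        r = (xc * gc).sum(0) / np.sqrt((xc**2).sum(0) * (gc**2).sum(0))
        assert np.all(np.abs(r - 0.5) < tol)


def test_simulation_determinism_under_seed():
    cfg = pg.SimulationConfig(n_offspring=500, n_snps=40, n_causal=5, seed=77)
    a = pg.simulate_cohort(cfg)
    b = pg.simulate_cohort(pg.SimulationConfig(n_offspring=500, n_snps=40, n_causal=5, seed=77))
    assert np.array_equal(a.offspring_dosage, b.offspring_dosage)
    assert np.array_equal(a.maternal_status, b.maternal_status, equal_nan=True)
    assert a.exclusions == b.exclusions  # exclusion counts exactly reproducible
    c = pg.simulate_cohort(pg.SimulationConfig(n_offspring=500, n_snps=40, n_causal=5, seed=78))
    assert not np.array_equal(a.offspring_dosage, c.offspring_dosage)


@pytest.mark.parametrize("parent,k", [("maternal", 0.096), ("paternal", 0.055)])
def test_prevalence_calibration_null_model(parent, k):
    """Intercept-only disease model reproduces the configured prevalence."""
    cfg = pg.SimulationConfig(n_offspring=30_000, n_snps=10, n_causal=0, seed=8)
    c = pg.simulate_trio_genotypes(cfg)
    status = pg.simulate_parent_disease(c, cfg, parent)
    tol = 3 * np.sqrt(k * (1 - k) / cfg.n_offspring)
    assert status.mean() == pytest.approx(k, abs=tol)


def test_prevalence_ratio_matches_configured_seventeen_fold():
    """Maternal/paternal prevalence ratio ~ 0.096/0.055 = 1.7."""
    cfg = pg.SimulationConfig(n_offspring=30_000, n_snps=20, n_causal=5, seed=9)
    c = pg.simulate_trio_genotypes(cfg)
    m = pg.simulate_parent_disease(c, cfg, "maternal")
    p = pg.simulate_parent_disease(c, cfg, "paternal")
    ratio = m.mean() / p.mean()
    assert ratio == pytest.approx(0.096 / 0.055, abs=0.15)
    assert round(ratio, 1) in (1.6, 1.7, 1.8)


def test_calibration_with_effects_preserves_prevalence(mid_cohort):
    """With causal effects present, the calibrated intercept still yields the
    target population prevalence."""
    c = mid_cohort
    k = c.config.k_maternal
    tol = 3 * np.sqrt(k * (1 - k) / c.n_offspring)
    assert c.maternal_true.mean() == pytest.approx(k, abs=tol)


def test_true_allelic_or_null_and_causal(mid_cohort):
    c = mid_cohort
    null_j = int(next(j for j in range(c.n_snps) if j not in set(c.causal_idx)))
    assert pg.true_allelic_or(c, null_j, "maternal", method="exact") == pytest.approx(1.0, abs=1e-9)
    causal_j = int(c.causal_idx[0])
    exact = pg.true_allelic_or(c, causal_j, "maternal", method="exact")
    tab = pg.true_allelic_or(c, causal_j, "maternal", method="tabulate", n_pop=400_000)
    # conditional OR 1.5; marginal allelic OR is attenuated a few percent
    assert 1.30 < exact < 1.52
    assert tab == pytest.approx(exact, rel=0.03)


def test_true_allelic_or_monomorphic_flagged(mid_cohort):
    c = mid_cohort
    c2 = pg.simulate_trio_genotypes(
        pg.SimulationConfig(n_offspring=100, n_snps=5, n_causal=0, seed=3)
    )
    pg.simulate_parent_disease(c2, c2.config, "maternal")
    c2.variants.loc[0, "MAF"] = 0.0
    with pytest.warns(UserWarning):
        assert np.isnan(pg.true_allelic_or(c2, 0, "maternal"))
    with pytest.raises(IndexError):
        pg.true_allelic_or(c, c.n_snps)


def test_perfect_reporting_identity():
    """sensitivity = specificity = 1 and no exclusions => observed == true."""
    cfg = pg.SimulationConfig(
        n_offspring=5_000, n_snps=20, n_causal=0,
        report_sensitivity=1.0, report_specificity=1.0,
        p_death_before_60=0.0, p_missing_age=0.0,
        parent_age_mean=80.0, parent_age_sd=3.0, seed=10,
    )
    c = pg.simulate_cohort(cfg)
    assert np.array_equal(c.maternal_status, c.maternal_true.astype(float))
    assert np.array_equal(c.paternal_status, c.paternal_true.astype(float))
    assert c.exclusions["maternal"]["excluded_total"] == 0


def test_all_young_parents_all_missing():
    cfg = pg.SimulationConfig(
        n_offspring=300, n_snps=10, n_causal=0,
        parent_age_mean=45.0, parent_age_sd=1.0, p_death_before_60=0.0, seed=11,
    )
    with pytest.warns(UserWarning):
        c = pg.simulate_cohort(cfg)
    assert np.all(np.isnan(c.maternal_status))
    assert c.exclusions["maternal"]["analyzed"] == 0


def test_sensitivity_binomially_thins_cases():
    """With sensitivity 0.8, ~80% of true cases are reported."""
    cfg = pg.SimulationConfig(
        n_offspring=40_000, n_snps=5, n_causal=0, k_maternal=0.5, k_paternal=0.25,
        report_sensitivity=0.8, report_specificity=1.0,
        p_death_before_60=0.0, p_missing_age=0.0, parent_age_mean=80.0, seed=12,
    )
    c = pg.simulate_cohort(cfg)
    n_true = int(c.maternal_true.sum())
    n_rep = int(np.nansum(c.maternal_status))
    se = np.sqrt(n_true * 0.8 * 0.2)
    assert abs(n_rep - 0.8 * n_true) < 4 * se


def test_exclusion_counts_match_masking():
    cfg = pg.SimulationConfig(n_offspring=3_000, n_snps=10, n_causal=0, seed=13)
    c = pg.simulate_cohort(cfg)
    for parent in ("maternal", "paternal"):
        counts = c.exclusions[parent]
        missing = int(np.isnan(c.status(parent)).sum())
        assert counts["excluded_total"] == missing
        assert counts["analyzed"] == c.n_offspring - missing
        assert (
            counts["age_under_60"] + counts["died_before_60"] <= counts["excluded_total"]
        )
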