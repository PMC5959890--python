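"""Shared fixtures: session-scoped simulated cohorts reused across tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import proxygwas as pg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mid_cohort():
    """Well-powered cohort: 20,000 offspring, 200 SNPs, 10 causal SNPs with
    parental allelic OR 1.5, perfect reporting and no exclusions (isolates
    the genetics from reporting artifacts)."""
    cfg = pg.SimulationConfig(
        n_offspring=20_000,
        n_snps=200,
        n_causal=10,
        causal_log_or=float(np.log(1.5)),
        maf_range=(0.1, 0.5),
        report_sensitivity=1.0,
        report_specificity=1.0,
        p_death_before_60=0.0,
        p_missing_age=0.0,
        seed=1234,
    )
    return pg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Fully null cohort (no causal SNPs) under the default reporting and
    exclusion conditions."""
    cfg = pg.SimulationConfig(n_offspring=4_000, n_snps=2_000, n_causal=0, seed=4321)
    return pg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mid_tables(mid_cohort):
    """Maternal/paternal GWAS and transformed tables for the mid cohort."""
    mat = pg.run_proxy_gwas(mid_cohort, "maternal")
    pat = pg.run_proxy_gwas(mid_cohort, "paternal")
    mt = pg.transform_table(mat, k=mat.attrs["prevalence"])
    pt = pg.transform_table(pat, k=pat.attrs["prevalence"])
    return {"maternal": mat, "paternal": pat, "maternal_or": mt, "paternal_or": pt}
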