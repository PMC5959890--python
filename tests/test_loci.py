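"""Locus definition: LD computation and the greedy clumping hierarchy
validated against exhaustive enumeration on small instances."""

import itertools

import numpy as np
import pandas as pd
import pytest

import proxygwas as pg
from proxygwas.loci import LDMatrix


def make_ld(r2_matrix, bp=None, chrom="1"):
    m = r2_matrix.shape[0]
    bp = np.arange(1, m + 1) * 10_000 if bp is None else np.asarray(bp)
    return LDMatrix(
        snps=[f"v{i}" for i in range(m)],
        chrom=np.array([chrom] * m),
        bp=bp.astype(np.int64),
        r=np.sqrt(r2_matrix),
    )


def make_stats(p, bp=None, chrom="1"):
    m = len(p)
    bp = np.arange(1, m + 1) * 10_000 if bp is None else np.asarray(bp)
    return pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "CHR": chrom, "BP": bp, "P": p}
    )


def brute_force_selection(stats, ld, p_threshold, r2_thresh):
    """Exhaustive check: enumerate all subsets of significant SNPs and find
    the unique one consistent with the selection rule (a SNP is in the set
    iff, in ascending-p order, it is below the LD threshold with every
    smaller-p member)."""
    sig = stats.loc[stats["P"] < p_threshold].sort_values(["P", "BP", "SNP"])
    ids = sig["SNP"].tolist()
    solutions = []
    for k in range(len(ids) + 1):
        for sub in itertools.combinations(ids, k):
            chosen = []
            consistent = True
            for s in ids:
                blocked = any(
                    ld.r2[ld.index(s), ld.index(t)] >= r2_thresh for t in chosen
                )
                if (s in sub) != (not blocked):
                    consistent = False
                    break
                if not blocked:
                    chosen.append(s)
            if consistent:
                solutions.append(sorted(sub))
    assert len(solutions) == 1, "selection rule must have a unique solution"
    return solutions[0]


def test_compute_ld_basic_properties():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(200, 4)).astype(float)
    d[:, 3] = d[:, 2]  # duplicated column
    var = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(4)], "CHR": "1", "BP": [1, 2, 3, 4], "A1": "A", "A2": "G", "MAF": 0.3}
    )
    ld = pg.compute_ld(d, var)
    assert np.allclose(np.diag(ld.r2), 1.0)
    assert ld.r2[2, 3] == pytest.approx(1.0)
    assert np.allclose(ld.r2, ld.r2.T)
    assert ((ld.r2 >= 0) & (ld.r2 <= 1 + 1e-12)).all()


def test_compute_ld_independent_snps_near_zero():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.4, size=(10_000, 2)).astype(float)
    var = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "BP": [1, 2], "MAF": 0.4})
    ld = pg.compute_ld(d, var)
    assert ld.r2[0, 1] < 0.01


def test_compute_ld_window_and_monomorphic():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
    d[:, 1] = 1.0  # monomorphic
    var = pd.DataFrame(
        {"SNP": ["a", "b", "c"], "CHR": "1", "BP": [1, 2, 5_000_000], "MAF": 0.3}
    )
    with pytest.warns(UserWarning, match="monomorphic"):
        ld = pg.compute_ld(d, var, window_bp=1_000_000)
    assert ld.r2[0, 2] == 0.0  # beyond window
    assert np.isnan(ld.r2[0, 1]) and ld.monomorphic == ["b"]
    assert ld.r2[1, 1] == 1.0  # diagonal stays defined


def test_independent_significant_trivial_cases():
    r2 = np.eye(3)
    r2[0, 1] = r2[1, 0] = 0.9
    ld = make_ld(r2)
    stats = make_stats([1e-10, 1e-9, 0.5])
    sel, assign = pg.independent_significant(stats, ld)
    assert sel == ["v0"]  # v1 blocked by r2=0.9, v2 not significant
    assert assign == {"v0": "v0", "v1": "v0"}
    empty, _ = pg.independent_significant(make_stats([0.2, 0.3, 0.4]), ld)
    assert empty == []


@pytest.mark.parametrize("seed", range(6))
def test_greedy_selection_matches_exhaustive_enumeration(seed):
    """Random <=8-SNP instances: greedy equals the unique rule-consistent
    subset found by brute force, for both thresholds."""
    rng = np.random.default_rng(seed)
    m = 8
    dos = rng.binomial(2, rng.uniform(0.2, 0.5), size=(60, m)).astype(float)
    # plant some LD by copying columns with noise
    for j in (1, 4, 6):
        src = dos[:, j - 1]
        flip = rng.random(60) < 0.15
        dos[:, j] = np.where(flip, rng.binomial(2, 0.35, 60), src)
    var = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "CHR": "1", "BP": np.arange(1, m + 1) * 10_000, "MAF": 0.3}
    )
    ld = pg.compute_ld(dos, var)
    p = rng.uniform(1e-12, 1e-7, size=m)
    p[rng.random(m) < 0.3] = rng.uniform(0.01, 1)
    stats = make_stats(p)

    sel, _ = pg.independent_significant(stats, ld, 5e-8, 0.6)
    assert sorted(sel) == brute_force_selection(stats, ld, 5e-8, 0.6)
    leads, _ = pg.lead_snps(sel, stats, ld, 0.1)
    lead_stats = stats[stats["SNP"].isin(sel)]
    assert sorted(leads) == brute_force_selection(lead_stats, ld, np.inf, 0.1)


def test_planted_blocks_instance():
    """Three LD blocks: {0,1,2} tight, {3,4} moderate, {5} free."""
    r2 = np.eye(6)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        r2[i, j] = r2[j, i] = 0.9
    r2[3, 4] = r2[4, 3] = 0.7
    # cross-block LD moderate: 0.3 between blocks 1 and 2
    for i in (0, 1, 2):
        for j in (3, 4):
            r2[i, j] = r2[j, i] = 0.3
    ld = make_ld(r2)
    stats = make_stats([1e-12, 1e-10, 1e-9, 1e-11, 1e-8, 2e-9])
    sel, _ = pg.independent_significant(stats, ld)
    assert sorted(sel) == brute_force_selection(stats, ld, 5e-8, 0.6)
    assert sorted(sel) == ["v0", "v3", "v5"]
    leads, _ = pg.lead_snps(sel, stats, ld)
    # v0-v3 r2 = 0.3 >= 0.1 -> one lead among them; v5 independent (r2 0)
    assert sorted(leads) == ["v0", "v5"]


def test_single_isolated_snp_locus():
    ld = make_ld(np.eye(1), bp=[123_456])
    stats = make_stats([1e-10], bp=[123_456])
    sel, _ = pg.independent_significant(stats, ld)
    leads, lead_of = pg.lead_snps(sel, stats, ld)
    loci = pg.define_loci(leads, sel, stats, ld)
    assert len(loci) == 1
    assert loci[0].start == loci[0].end == 123_456
    assert loci[0].member_snps == ["v0"]


def test_two_leads_within_window_merge():
    """Leads 100 kb apart form one locus; 2 Mb apart form two."""
    r2 = np.eye(2)
    for gap, expected in [(100_000, 1), (2_000_000, 2)]:
        bp = np.array([1_000_000, 1_000_000 + gap])
        ld = make_ld(r2, bp=bp)
        stats = make_stats([1e-10, 1e-9], bp=bp)
        sel, _ = pg.independent_significant(stats, ld)
        leads, lead_of = pg.lead_snps(sel, stats, ld)
        loci = pg.define_loci(leads, sel, stats, ld)
        assert len(loci) == expected


def test_merge_is_transitive_chain():
    """Leads at 0/200k/400k: pairwise windows chain into a single locus."""
    r2 = np.eye(3)
    bp = np.array([1, 200_001, 400_001])
    ld = make_ld(r2, bp=bp)
    stats = make_stats([1e-10, 1e-11, 1e-9], bp=bp)
    sel, _ = pg.independent_significant(stats, ld)
    leads, _ = pg.lead_snps(sel, stats, ld)
    loci = pg.define_loci(leads, sel, stats, ld)
    assert len(loci) == 1
    assert loci[0].start == 1 and loci[0].end == 400_001


def test_members_and_exclusive_assignment():
    """Members are SNPs with r2 >= 0.6 to an independent SNP, regardless of
    significance; every significant SNP lands in exactly one locus."""
    m = 6
    r2 = np.eye(m)
    r2[0, 1] = r2[1, 0] = 0.8  # v1 member of v0's locus (not significant)
    r2[3, 4] = r2[4, 3] = 0.65
    bp = np.array([1, 2, 3_000_000, 6_000_000, 6_000_010, 9_000_000])
    ld = make_ld(r2, bp=bp)
    stats = make_stats([1e-10, 0.5, 0.9, 1e-9, 1e-8, 0.2], bp=bp)
    sel, assign = pg.independent_significant(stats, ld)
    leads, lead_of = pg.lead_snps(sel, stats, ld)
    loci = pg.define_loci(leads, sel, stats, ld)
    member_union = [s for L in loci for s in L.member_snps]
    assert len(member_union) == len(set(member_union))  # disjoint
    sig = set(stats.loc[stats["P"] < 5e-8, "SNP"])
    assert sig <= set(member_union)  # every significant SNP in exactly one locus
    by_snp = {s: L.locus_id for L in loci for s in L.member_snps}
    assert by_snp["v1"] == by_snp["v0"]
    assert by_snp["v4"] == by_snp["v3"]


def test_lead_snps_pairwise_constraint(mid_tables):
    """Selected leads are pairwise below the r2 threshold on a simulated
    panel (structural invariant)."""
    rng = np.random.default_rng(3)
    m = 12
    dos = rng.binomial(2, 0.3, size=(500, m)).astype(float)
    dos[:, 1] = dos[:, 0]
    var = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "CHR": "1", "BP": np.arange(1, m + 1) * 1_000, "MAF": 0.3}
    )
    ld = pg.compute_ld(dos, var)
    stats = make_stats(rng.uniform(1e-12, 1e-9, m), bp=var["BP"].to_numpy())
    sel, _ = pg.independent_significant(stats, ld)
    for a, b in itertools.combinations(sel, 2):
        assert ld.r2[ld.index(a), ld.index(b)] < 0.6
    leads, _ = pg.lead_snps(sel, stats, ld)
    for a, b in itertools.combinations(leads, 2):
        assert ld.r2[ld.index(a), ld.index(b)] < 0.1


def test_locus_table_report_columns():
    r2 = np.eye(2)
    bp = np.array([100, 200])
    ld = make_ld(r2, bp=bp)
    stats = make_stats([1e-10, 1e-9], bp=bp)
    stats["A1"], stats["A2"], stats["FREQ"] = "A", "G", 0.3
    stats["OR"], stats["L95"], stats["U95"], stats["DIRECTION"] = 1.06, 1.04, 1.07, "++?+"
    sel, _ = pg.independent_significant(stats, ld)
    leads, _ = pg.lead_snps(sel, stats, ld)
    loci = pg.define_loci(leads, sel, stats, ld)
    table = pg.locus_table(loci, stats)
    assert table.loc[0, "OR_95CI"] == "1.06 (1.04, 1.07)"
    assert table.loc[0, "LOCUS_START"] <= table.loc[0, "LOCUS_END"]
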