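"""Genomic risk-locus definition from summary statistics and a reference
LD panel, following the FUMA-style rules: independent significant SNPs
(P < 5e-8, pairwise r2 < 0.6), lead SNPs (independent SNPs pairwise
r2 < 0.1), and loci formed by merging lead SNPs within a 250 kb window
together with every SNP in LD (r2 >= 0.6) with one of the locus's
independent significant SNPs. Positions are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LDMatrix:
    """Pairwise LD from a reference dosage panel.

    ``r`` holds signed Pearson correlations (used by the gene-based null);
    ``r2`` is its elementwise square. SNPs are ordered by position.
    """

    snps: list[str]
    chrom: np.ndarray
    bp: np.ndarray
    r: np.ndarray
    monomorphic: list[str] = field(default_factory=list)

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index(self, snp: str) -> int:
        try:
            return self._lookup[snp]
        except AttributeError:
            self._lookup = {s: i for i, s in enumerate(self.snps)}
            return self._lookup[snp]

    def submatrix(self, snps: list[str]) -> np.ndarray:
        idx = [self.index(s) for s in snps]
        return self.r[np.ix_(idx, idx)]


def compute_ld(dosages: np.ndarray, variants: pd.DataFrame, window_bp: int = 1_000_000) -> LDMatrix:
    """Signed dosage correlations within a base-pair window.

    Pairs beyond the window (or on different chromosomes) are set to 0;
    monomorphic SNPs get NaN rows and are flagged. Requires at least two
    individuals and positionally sorted SNPs.
    """
    dosages = np.asarray(dosages, float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("reference panel needs >= 2 individuals")
    bp = variants["BP"].to_numpy()
    chrom = variants["CHR"].to_numpy(str)
    order_ok = all(
        bp[i] <= bp[i + 1] for i in range(len(bp) - 1) if chrom[i] == chrom[i + 1]
    )
    if not order_ok:
        raise ValueError("variants must be sorted by position within chromosome")
    sd = dosages.std(axis=0)
    mono = sd == 0.0
    monomorphic = variants.loc[mono, "SNP"].tolist()
    if monomorphic:
        warnings.warn(f"{len(monomorphic)} monomorphic SNPs have undefined LD (NaN rows)")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(dosages, rowvar=False)
    r = np.atleast_2d(r)
    same_chrom = chrom[:, None] == chrom[None, :]
    in_window = np.abs(bp[:, None] - bp[None, :]) <= window_bp
    r[~(same_chrom & in_window)] = 0.0
    r[mono, :] = np.nan
    r[:, mono] = np.nan
    np.fill_diagonal(r, 1.0)
    return LDMatrix(
        snps=variants["SNP"].tolist(), chrom=chrom, bp=bp.astype(np.int64), r=r, monomorphic=monomorphic
    )


@dataclass
class Locus:
    locus_id: int
    chrom: str
    start: int  # 1-based inclusive
    end: int
    lead_snps: list[str]
    independent_snps: list[str]
    member_snps: list[str]
    top_lead: str
    top_p: float


def _greedy_order(stats: pd.DataFrame) -> pd.DataFrame:
    """Ascending p, ties broken by ascending bp then lexicographic SNP id."""
    return stats.sort_values(["P", "BP", "SNP"], kind="mergesort")


def independent_significant(
    stats: pd.DataFrame, ld: LDMatrix, p_threshold: float = 5e-8, r2_indep: float = 0.6
) -> tuple[list[str], dict[str, str]]:
    """Greedy selection of independent significant SNPs.

    A significant SNP (P < p_threshold) enters the set iff its r2 with every
    already-selected SNP is below ``r2_indep``; significant SNPs that do not
    enter are assigned to the selected SNP that blocked them (smallest-p one).
    Returns (selected ids in selection order, assignment map).
    """
    sig = _greedy_order(stats.loc[stats["P"] < p_threshold])
    selected: list[str] = []
    sel_idx: list[int] = []
    assignment: dict[str, str] = {}
    r2 = ld.r2
    for snp in sig["SNP"]:
        i = ld.index(snp)
        if sel_idx:
            corr = r2[i, sel_idx]
            blocked = np.flatnonzero(corr >= r2_indep)
        else:
            blocked = np.empty(0, int)
        if blocked.size == 0:
            selected.append(snp)
            sel_idx.append(i)
            assignment[snp] = snp
        else:
            assignment[snp] = selected[blocked[0]]  # earliest selected = smallest p
    return selected, assignment


def lead_snps(
    independent: list[str], stats: pd.DataFrame, ld: LDMatrix, r2_lead: float = 0.1
) -> tuple[list[str], dict[str, str]]:
    """Greedy lead-SNP selection within the independent set (pairwise
    r2 < ``r2_lead``); non-lead independents are assigned to the lead that
    blocked them."""
    pool = _greedy_order(stats.loc[stats["SNP"].isin(independent)])
    leads: list[str] = []
    lead_idx: list[int] = []
    lead_of: dict[str, str] = {}
    r2 = ld.r2
    for snp in pool["SNP"]:
        i = ld.index(snp)
        if lead_idx:
            blocked = np.flatnonzero(r2[i, lead_idx] >= r2_lead)
        else:
            blocked = np.empty(0, int)
        if blocked.size == 0:
            leads.append(snp)
            lead_idx.append(i)
            lead_of[snp] = snp
        else:
            lead_of[snp] = leads[blocked[0]]
    return leads, lead_of


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def define_loci(
    leads: list[str],
    independent: list[str],
    stats: pd.DataFrame,
    ld: LDMatrix,
    merge_window_bp: int = 250_000,
    r2_member: float = 0.6,
    lead_of: dict[str, str] | None = None,
) -> list[Locus]:
    """Merge lead SNPs within ``merge_window_bp`` (between lead positions,
    iterated to closure) into loci; members are all panel SNPs with
    r2 >= ``r2_member`` to any independent significant SNP of the locus.
    Member significance is not required. Loci on one chromosome are
    disjoint in membership; a SNP reachable from two loci joins the one
    with the smaller top-lead p."""
    if not leads:
        return []
    if lead_of is None:
        _, lead_of = lead_snps(independent, stats, ld, r2_lead=0.1)

    pos = {s: int(ld.bp[ld.index(s)]) for s in leads}
    chrom = {s: str(ld.chrom[ld.index(s)]) for s in leads}
    uf = _UnionFind(leads)
    for i, a in enumerate(leads):
        for b in leads[i + 1 :]:
            if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= merge_window_bp:
                uf.union(a, b)

    groups: dict[str, list[str]] = {}
    for s in leads:
        groups.setdefault(uf.find(s), []).append(s)

    pmap = dict(zip(stats["SNP"], stats["P"]))
    r2 = ld.r2
    proto = []
    for group in groups.values():
        indep = [s for s in independent if lead_of.get(s) in group]
        top = min(group, key=lambda s: (pmap.get(s, np.inf), pos[s], s))
        proto.append((pmap.get(top, np.inf), group, indep, top))
    proto.sort(key=lambda t: t[0])

    claimed: set[str] = set()
    loci: list[Locus] = []
    for top_p, group, indep, top in proto:
        idx = [ld.index(s) for s in indep]
        member_mask = np.zeros(len(ld.snps), dtype=bool)
        if idx:
            with np.errstate(invalid="ignore"):
                member_mask = np.nanmax(r2[np.ix_(range(len(ld.snps)), idx)], axis=1) >= r2_member
        members = [s for s, m in zip(ld.snps, member_mask) if m and s not in claimed]
        for s in group + indep:
            if s not in claimed and s not in members:
                members.append(s)
        claimed.update(members)
        mpos = [int(ld.bp[ld.index(s)]) for s in members]
        loci.append(
            Locus(
                locus_id=0,
                chrom=chrom[group[0]],
                start=min(mpos),
                end=max(mpos),
                lead_snps=sorted(group, key=lambda s: pos[s]),
                independent_snps=indep,
                member_snps=members,
                top_lead=top,
                top_p=float(top_p),
            )
        )
    loci.sort(key=lambda L: (L.chrom, L.start))
    for i, L in enumerate(loci, start=1):
        L.locus_id = i
    return loci


def locus_table(loci: list[Locus], stats: pd.DataFrame) -> pd.DataFrame:
    """Report-style locus table (one row per locus, keyed by the top lead)."""
    from .lmor import format_or_ci

    rows = []
    s = stats.set_index("SNP")
    for L in loci:
        row = {
            "LOCUS": L.locus_id,
            "CHR": L.chrom,
            "LEAD_SNP": L.top_lead,
            "N_LEADS": len(L.lead_snps),
            "N_INDEPENDENT": len(L.independent_snps),
            "N_MEMBERS": len(L.member_snps),
            "LOCUS_START": L.start,
            "LOCUS_END": L.end,
            "P": L.top_p,
        }
        if L.top_lead in s.index:
            rec = s.loc[L.top_lead]
            for col in ("A1", "A2", "BP", "FREQ", "DIRECTION"):
                if col in s.columns:
                    row[col] = rec[col]
            if {"OR", "L95", "U95"}.issubset(s.columns):
                row["OR_95CI"] = format_or_ci(rec["OR"], rec["L95"], rec["U95"])
        rows.append(row)
    return pd.DataFrame(rows)
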