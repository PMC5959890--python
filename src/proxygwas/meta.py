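"""Fixed-effects inverse-variance (SE-weighted) meta-analysis with the
staged design used for the family-history AD analysis.

The staging: the two UK-Biobank proxy GWAS (maternal, paternal) are
combined first; the result is then combined with the case-control
consortium's stage-2 summary output where a SNP has stage-2 results, and
with the stage-1 output otherwise. Because fixed-effects IVW is
associative, the staged combination equals a one-step IVW over the
contributing cohorts; the staging matters only for which consortium effect
is eligible. A four-character direction string records each cohort's effect
sign in the fixed order (UKB maternal, UKB paternal, stage 1, stage 2),
with '?' where a cohort did not contribute the SNP.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr

log = logging.getLogger(__name__)

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _effect_se(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Pick the effect/SE columns: transformed tables carry LOG_OR/SE_LOGOR,
    linear tables BETA/SE."""
    if "LOG_OR" in df.columns:
        return df["LOG_OR"], df["SE_LOGOR"]
    if "BETA" in df.columns:
        return df["BETA"], df["SE"]
    raise ValueError("table has neither LOG_OR nor BETA effect columns")


def ivw_meta(effects) -> tuple[float, float, float, float]:
    """Inverse-variance weighted fixed-effects combination.

    ``effects`` is an iterable of (effect, se) pairs; weights are 1/se^2.
    Returns (effect, se, z, p) with a two-sided normal p-value.
    """
    arr = np.asarray(list(effects), float)
    if arr.size == 0:
        raise ValueError("ivw_meta requires at least one effect")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("effects must be (effect, se) pairs")
    e, se = arr[:, 0], arr[:, 1]
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / se**2
    eff = float(np.sum(w * e) / np.sum(w))
    se_m = float(np.sum(w) ** -0.5)
    z = eff / se_m
    p = float(max(2.0 * ndtr(-abs(z)), np.finfo(float).tiny))
    return eff, se_m, float(z), p


def harmonize_effect(effect, a1, a2, ref_a1, ref_a2):
    """Align an effect to reference alleles: unchanged on exact match,
    sign-flipped when alleles are swapped, None when unreconcilable."""
    if a1 == ref_a1 and a2 == ref_a2:
        return effect
    if a1 == ref_a2 and a2 == ref_a1:
        return -effect
    return None


_TAGS = ("m", "p", "s1", "s2")


def staged_meta(
    ukb_maternal: pd.DataFrame,
    ukb_paternal: pd.DataFrame,
    igap_stage1: pd.DataFrame | None = None,
    igap_stage2: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Staged SE-weighted meta-analysis over up to four cohorts.

    Alleles are harmonized to the first cohort carrying each SNP (in the
    order maternal, paternal, stage 1, stage 2); swapped alleles are
    sign-flipped, unreconcilable rows are excluded with a warning, and
    palindromic (A/T, C/G) reference pairs pass through with a warning.
    Stage-1 effects enter the combination only for SNPs absent from stage 2,
    mirroring the staged input actually given to the meta-analysis; the
    direction string shows '?' for any cohort that did not contribute.
    """
    tables = dict(zip(_TAGS, (ukb_maternal, ukb_paternal, igap_stage1, igap_stage2)))
    frames = {}
    for tag, df in tables.items():
        if df is None:
            continue
        e, se = _effect_se(df)
        f = pd.DataFrame(
            {
                f"E_{tag}": e.to_numpy(float),
                f"SE_{tag}": se.to_numpy(float),
                f"A1_{tag}": df["A1"].astype(str).str.upper().to_numpy(),
                f"A2_{tag}": df["A2"].astype(str).str.upper().to_numpy(),
            },
            index=pd.Index(df["SNP"], name="SNP"),
        )
        for extra in ("CHR", "BP", "FREQ", "N"):
            if extra in df.columns:
                f[f"{extra}_{tag}"] = df[extra].to_numpy()
        frames[tag] = f
    if not any(t in frames for t in ("m", "p")):
        raise ValueError("at least one UK Biobank cohort table is required")

    merged = pd.concat(frames.values(), axis=1, join="outer")
    present = {tag: merged.get(f"E_{tag}", pd.Series(np.nan, index=merged.index)).notna() for tag in _TAGS}

    # reference alleles: first cohort carrying the SNP
    ref_a1 = pd.Series(pd.NA, index=merged.index, dtype=object)
    ref_a2 = pd.Series(pd.NA, index=merged.index, dtype=object)
    for tag in _TAGS:
        if tag not in frames:
            continue
        fill = ref_a1.isna() & present[tag]
        ref_a1[fill] = merged.loc[fill, f"A1_{tag}"]
        ref_a2[fill] = merged.loc[fill, f"A2_{tag}"]

    n_palindromic = int(
        sum(1 for a, b in zip(ref_a1, ref_a2) if isinstance(a, str) and (a, b) in _PALINDROMIC)
    )
    if n_palindromic:
        log.warning(
            "%d palindromic (A/T or C/G) SNPs pass through without frequency-based "
            "strand resolution", n_palindromic,
        )

    mismatch = pd.Series(False, index=merged.index)
    eff = {}
    for tag in _TAGS:
        if tag not in frames:
            eff[tag] = pd.Series(np.nan, index=merged.index)
            continue
        a1 = merged[f"A1_{tag}"]
        a2 = merged[f"A2_{tag}"]
        match = (a1 == ref_a1) & (a2 == ref_a2)
        flip = (a1 == ref_a2) & (a2 == ref_a1)
        bad = present[tag] & ~match & ~flip
        mismatch |= bad
        e = merged[f"E_{tag}"].where(~flip, -merged[f"E_{tag}"])
        eff[tag] = e
    if mismatch.any():
        log.warning("excluding %d SNPs with unreconcilable alleles", int(mismatch.sum()))
        merged = merged[~mismatch]
        ref_a1, ref_a2 = ref_a1[~mismatch], ref_a2[~mismatch]
        eff = {t: e[~mismatch] for t, e in eff.items()}
        present = {t: p[~mismatch] for t, p in present.items()}

    # contributing effects: maternal, paternal, and stage 2 preferred over stage 1
    use = {
        "m": present["m"],
        "p": present["p"],
        "s1": present["s1"] & ~present["s2"],
        "s2": present["s2"],
    }
    w_sum = pd.Series(0.0, index=merged.index)
    we_sum = pd.Series(0.0, index=merged.index)
    n_cohorts = pd.Series(0, index=merged.index)
    for tag in _TAGS:
        if tag not in frames:
            continue
        w = (1.0 / merged[f"SE_{tag}"] ** 2).where(use[tag], 0.0)
        w_sum += w.fillna(0.0)
        we_sum += (w * eff[tag]).fillna(0.0)
        n_cohorts += use[tag].astype(int)

    keep = w_sum > 0
    merged, ref_a1, ref_a2 = merged[keep], ref_a1[keep], ref_a2[keep]
    eff = {t: e[keep] for t, e in eff.items()}
    use = {t: u[keep] for t, u in use.items()}
    w_sum, we_sum, n_cohorts = w_sum[keep], we_sum[keep], n_cohorts[keep]

    log_or = we_sum / w_sum
    se = w_sum**-0.5
    z = log_or / se
    p = np.maximum(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny)

    def _dir(tag: str) -> np.ndarray:
        signs = np.where(eff[tag].to_numpy(float) < 0, "-", "+")
        return np.where(use[tag].to_numpy(bool), signs, "?")

    direction = np.char.add(np.char.add(_dir("m"), _dir("p")), np.char.add(_dir("s1"), _dir("s2")))

    out = pd.DataFrame(
        {
            "SNP": merged.index.to_numpy(),
            "A1": ref_a1.to_numpy(),
            "A2": ref_a2.to_numpy(),
            "LOG_OR": log_or.to_numpy(),
            "SE_LOGOR": se.to_numpy(),
            "Z": z.to_numpy(),
            "P": p,
            "DIRECTION": direction,
            "N_COHORTS": n_cohorts.to_numpy(),
        }
    )
    for extra in ("CHR", "BP", "FREQ"):
        cols = [f"{extra}_{t}" for t in _TAGS if f"{extra}_{t}" in merged.columns]
        if cols:
            out[extra] = merged[cols].bfill(axis=1).iloc[:, 0].to_numpy()
    n_cols = [f"N_{t}" for t in _TAGS if f"N_{t}" in merged.columns]
    if n_cols:
        # total analyzed sample size over contributing cohorts
        n_tot = pd.Series(0.0, index=merged.index)
        for tag in _TAGS:
            if f"N_{tag}" in merged.columns:
                n_tot += pd.to_numeric(merged[f"N_{tag}"], errors="coerce").where(use[tag], 0.0).fillna(0.0)
        out["N"] = n_tot.to_numpy(np.int64)
    out["SE"] = out["SE_LOGOR"]  # dialect alias for downstream readers
    out["OR"] = np.exp(out["LOG_OR"])
    out["L95"] = np.exp(out["LOG_OR"] - 1.959963984540054 * out["SE_LOGOR"])
    out["U95"] = np.exp(out["LOG_OR"] + 1.959963984540054 * out["SE_LOGOR"])
    out.attrs["n_excluded_allele_mismatch"] = int(mismatch.sum())
    out.attrs["n_palindromic"] = n_palindromic
    return out.reset_index(drop=True)


def sign_concordance(meta_a: pd.DataFrame, meta_b: pd.DataFrame, snps=None) -> tuple[int, int]:
    """Count SNPs whose effect signs agree between two tables after allele
    harmonization. Returns (n_concordant, n_total) over the shared set."""
    ea, _ = _effect_se(meta_a)
    eb, _ = _effect_se(meta_b)
    a = pd.DataFrame(
        {
            "E": ea.to_numpy(float),
            "A1": meta_a["A1"].astype(str).str.upper().to_numpy(),
            "A2": meta_a["A2"].astype(str).str.upper().to_numpy(),
        },
        index=pd.Index(meta_a["SNP"], name="SNP"),
    )
    b = pd.DataFrame(
        {
            "E": eb.to_numpy(float),
            "A1": meta_b["A1"].astype(str).str.upper().to_numpy(),
            "A2": meta_b["A2"].astype(str).str.upper().to_numpy(),
        },
        index=pd.Index(meta_b["SNP"], name="SNP"),
    )
    shared = a.index.intersection(b.index)
    if snps is not None:
        shared = shared.intersection(pd.Index(snps))
    if len(shared) == 0:
        raise ValueError("no shared SNPs between the two tables")
    a, b = a.loc[shared], b.loc[shared]
    e_b = np.array(
        [
            harmonize_effect(e, a1, a2, ra1, ra2)
            for e, a1, a2, ra1, ra2 in zip(b["E"], b["A1"], b["A2"], a["A1"], a["A2"])
        ],
        dtype=object,
    )
    usable = np.array([x is not None for x in e_b])
    if usable.sum() == 0:
        raise ValueError("no allele-reconcilable shared SNPs")
    eb_h = np.array([x for x in e_b[usable]], float)
    ea_v = a["E"].to_numpy(float)[usable]
    concordant = int(np.sum(np.sign(ea_v) == np.sign(eb_h)))
    return concordant, int(usable.sum())
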