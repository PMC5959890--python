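"""File formats: summary-statistics TSV, dosage matrices, gene annotation,
gene sets and a minimal VCF export.

The canonical interchange format is a tab-delimited summary-statistics
table with one header line and columns SNP, CHR, BP, A1, A2, FREQ, an
effect column (BETA and/or LOG_OR/OR), SE, Z, P, N and optionally
DIRECTION. Coordinates are 1-based inclusive, alleles upper-case, A1 is
always the effect allele. Reading and writing round-trips losslessly
(floats are written at full precision).
"""

from __future__ import annotations

import logging
import pathlib

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "SE", "P", "N"]
EFFECT_COLUMNS = ("BETA", "LOG_OR", "OR")

_FLOAT_COLS = ("FREQ", "BETA", "SE", "Z", "P", "OR", "LOG_OR", "SE_LOGOR", "L95", "U95", "MAF", "K")
_INT_COLS = ("BP", "N", "N_COHORTS", "NSNPS")
_STR_COLS = ("SNP", "CHR", "A1", "A2", "DIRECTION", "FLAG", "GENE", "METHOD")


class SummaryStatsError(ValueError):
    """Malformed or incomplete summary-statistics file."""


def _convert_column(df: pd.DataFrame, col: str, kind: str) -> None:
    raw = df[col]
    na = raw.isna() | raw.astype(str).str.upper().isin(["NA", "NAN", ""])
    converted = pd.to_numeric(raw.mask(na), errors="coerce")
    bad = converted.isna() & ~na
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SummaryStatsError(
            f"column {col}: malformed value {raw.iloc[i]!r} at line {i + 2}"
        )
    if kind == "int":
        if not na.any():
            frac = converted % 1
            if (frac != 0).any():
                i = int(np.flatnonzero((frac != 0).to_numpy())[0])
                raise SummaryStatsError(
                    f"column {col}: non-integer value {raw.iloc[i]!r} at line {i + 2}"
                )
            df[col] = converted.astype(np.int64)
        else:
            df[col] = converted
    else:
        # exact (correctly rounded) parse; pandas' fast parser can be off
        # in the last digit
        df[col] = raw.mask(na).astype(np.float64)


def read_summary_stats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV.

    ``column_map`` renames foreign headers (e.g. METAL-style) onto the
    canonical dialect before validation. Missing mandatory columns raise an
    error naming the column; malformed cells raise with the 1-based file
    line number. Unknown columns are preserved.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    if not any(c in df.columns for c in EFFECT_COLUMNS):
        raise SummaryStatsError(
            f"missing effect column: need one of {', '.join(EFFECT_COLUMNS)}"
        )
    for col in df.columns:
        if col in _STR_COLS:
            df[col] = df[col].astype(str)
            if col in ("A1", "A2"):
                df[col] = df[col].str.upper()
        elif col in _INT_COLS:
            _convert_column(df, col, "int")
        elif col in _FLOAT_COLS:
            _convert_column(df, col, "float")
        else:  # unknown column: numeric when possible, else left as text
            converted = pd.to_numeric(df[col], errors="coerce")
            if not (converted.isna() & df[col].notna()).any():
                df[col] = converted

    if (df["BP"] <= 0).any():
        i = int(np.flatnonzero((df["BP"] <= 0).to_numpy())[0])
        raise SummaryStatsError(f"column BP: non-positive position at line {i + 2}")
    bad_freq = ~((df["FREQ"] > 0) & (df["FREQ"] < 1))
    if bad_freq.any():
        i = int(np.flatnonzero(bad_freq.to_numpy())[0])
        raise SummaryStatsError(f"column FREQ: value outside (0,1) at line {i + 2}")
    log.info("read %d rows from %s", len(df), path)
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write the TSV dialect (full float precision; NA for missing)."""
    # %.17g guarantees float64 round-trip through text
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    log.info("wrote %d rows to %s", len(df), path)


# ------------------------------------------------------------ dosage matrix


def write_dosage_matrix(dosage: np.ndarray, variants: pd.DataFrame, outdir) -> None:
    """Plain tab-delimited dosage matrix (individuals x SNPs, header = SNP
    ids, first column IID) with a sidecar variant map (1-based positions)."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(dosage, columns=variants["SNP"].tolist())
    mat.insert(0, "IID", np.arange(dosage.shape[0]))
    mat.to_csv(outdir / "dosage.tsv", sep="\t", index=False)
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)


def read_dosage_matrix(indir) -> tuple[np.ndarray, pd.DataFrame]:
    indir = pathlib.Path(indir)
    mat = pd.read_csv(indir / "dosage.tsv", sep="\t")
    variants = pd.read_csv(indir / "variants.tsv", sep="\t", dtype={"CHR": str})
    dosage = mat.drop(columns="IID").to_numpy(np.int8)
    if list(mat.columns[1:]) != variants["SNP"].tolist():
        raise ValueError("dosage matrix columns do not match the variant map")
    return dosage, variants


def write_vcf(dosage: np.ndarray, variants: pd.DataFrame, path, sample_prefix: str = "S") -> None:
    """Minimal VCF 4.2 export with hard genotypes from 0/1/2 dosages.

    A1 (the effect allele) is written as ALT, A2 as REF, so the ALT dosage
    equals the stored dosage.
    """
    n = dosage.shape[0]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"{sample_prefix}{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in variants.reset_index(drop=True).iterrows():
            calls = "\t".join(gt[int(d)] for d in dosage[:, j])
            fh.write(
                f"{row['CHR']}\t{int(row['BP'])}\t{row['SNP']}\t{row['A2']}\t{row['A1']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ------------------------------------------------- annotation and gene sets


def read_gene_annotation(path) -> pd.DataFrame:
    """BED-like gene annotation: chr TAB start TAB end TAB gene-id, no
    header, 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 tab-separated fields")
            chrom, start, end, gene = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end}]")
            rows.append({"GENE": gene, "CHR": chrom, "START": start_i, "END": end_i})
    df = pd.DataFrame(rows)
    return df.sort_values(["CHR", "START"]).reset_index(drop=True)


def read_gene_sets(path) -> dict[str, list[str]]:
    """GMT-style gene sets: set-name TAB gene TAB gene ... (one per line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: set has no genes")
            sets[parts[0]] = parts[1:]
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, *genes]) + "\n")
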