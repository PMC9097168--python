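"""Readers and writers for the pipeline's plain-text dialects.

Catalog and eQTL tables are tab-separated; sweep windows are BED (0-based,
half-open); GWAS summaries are the usual SNP/beta/se/alleles/EAF TSV;
haplotype panels are a 0/1 matrix TSV with a variant header block.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ld import HaplotypePanel
from .sweep_overlap import GenomicWindow

__all__ = [
    "write_catalog", "read_catalog", "write_eqtls", "read_eqtls",
    "write_bed", "read_bed", "write_gwas", "read_gwas",
    "write_haplotypes", "read_haplotypes",
]

_NA = "."


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True,
                     dtype={"chrom": str})
    for col in ("rsid", "ancestral_allele"):
        if col in df:
            df[col] = df[col].where(df[col].notna(), None)
    # "." doubles as the missing-ancestral marker; genotypes keep "./." literally
    for col in ("gt_altai", "gt_vindija", "gt_denisova"):
        if col in df:
            df[col] = df[col].fillna("./.")
    return df


def write_eqtls(eqtls: pd.DataFrame, path) -> None:
    eqtls.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_eqtls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"chrom": str})
    if "qval_pass" in df:
        df["qval_pass"] = df["qval_pass"].astype(bool)
    if "rsid" in df:
        df["rsid"] = df["rsid"].where(df["rsid"].notna(), None)
    return df


def write_bed(windows: list[GenomicWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.source}\n")


def read_bed(path, source: str | None = None) -> list[GenomicWindow]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = source if source is not None else (parts[3] if len(parts) > 3 else "")
            out.append(GenomicWindow(chrom=parts[0], start=int(parts[1]),
                                     end=int(parts[2]), source=label))
    return out


def write_gwas(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_gwas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA])


def write_haplotypes(panel: HaplotypePanel, path) -> None:
    """Matrix TSV: three header rows (id, chrom, pos), then one row per haplotype."""
    with open(path, "w") as fh:
        fh.write("#id\t" + "\t".join(map(str, panel.ids)) + "\n")
        fh.write("#chrom\t" + "\t".join(map(str, panel.chrom)) + "\n")
        fh.write("#pos\t" + "\t".join(map(str, panel.pos)) + "\n")
        for row in panel.matrix:
            fh.write("h\t" + "\t".join(map(str, row)) + "\n")


def read_haplotypes(path) -> HaplotypePanel:
    with open(path) as fh:
        ids = np.array(fh.readline().rstrip("\n").split("\t")[1:])
        chrom = np.array(fh.readline().rstrip("\n").split("\t")[1:])
        pos = np.array(fh.readline().rstrip("\n").split("\t")[1:], dtype=np.int64)
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
    matrix = np.array(rows, dtype=np.uint8)
    return HaplotypePanel(matrix=matrix, chrom=chrom, pos=pos, ids=ids)
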