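"""Classify variants as *Homo sapiens*-derived, nearly-fixed alleles.

A site enters the derived high-frequency (HF) set when all of the following
hold:

1. the ancestral state is resolvable (great-ape alignment call, falling back
   to the macaque reference allele at ambiguous loci);
2. the derived allele is the major allele in modern humans and its global
   frequency is at or above the threshold (default 0.90) — and, in the
   stringent mode, at or above the threshold in each of the five
   metapopulations (AFR, AMR, EAS, EUR, SAS);
3. the archaic genotypes, restricted to individuals whose sequencing
   coverage is reliable (5–105× for the Altai Neanderthal, 5–75× for the
   Vindija Neanderthal and the Denisovan, inclusive), satisfy either
   (a) every reliable archaic is homozygous ancestral, or
   (b) the Denisovan is reliable and homozygous ancestral while at least one
   Neanderthal carries a derived allele — tolerating known gene flow from
   *Homo sapiens* into Neanderthals.

Sites with no reliable archaic genotype, or with an unresolvable ancestral
allele, are excluded from classification (``is_derived_hf = False`` with an
exclusion reason recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COVERAGE_BOUNDS",
    "METAPOPS",
    "coverage_pass",
    "assign_ancestral",
    "archaic_condition",
    "classify_record",
    "classify_catalog",
    "drop_unmapped",
]

#: Inclusive per-individual coverage bounds (sites outside are unreliable).
COVERAGE_BOUNDS = {"altai": (5, 105), "vindija": (5, 75), "denisova": (5, 75)}

METAPOPS = ("AFR", "AMR", "EAS", "EUR", "SAS")

ARCHAICS = ("altai", "vindija", "denisova")
NEANDERTHALS = ("altai", "vindija")

MISSING_GT = frozenset({"./.", ".", "", None})


def coverage_pass(dp_altai, dp_vindija, dp_denisova) -> dict[str, bool]:
    """Per-archaic coverage reliability plus an ``any`` summary.

    A missing coverage (None/NaN) fails; negative coverage is an error.
    """
    out = {}
    for name, dp in zip(ARCHAICS, (dp_altai, dp_vindija, dp_denisova)):
        if dp is None or (isinstance(dp, float) and np.isnan(dp)):
            out[name] = False
            continue
        dp = int(dp)
        if dp < 0:
            raise ValueError(f"negative coverage for {name}: {dp}")
        lo, hi = COVERAGE_BOUNDS[name]
        out[name] = lo <= dp <= hi
    out["any"] = any(out[a] for a in ARCHAICS)
    return out


def assign_ancestral(ape_call: str | None, macaque_allele: str | None,
                     ref: str, alt: str) -> tuple[str | None, str]:
    """Resolve the ancestral allele from the ape alignment, else macaque.

    Returns ``(ancestral_allele, source)`` where source is one of
    ``from_apes``, ``from_macaque``, ``unknown``, ``unresolvable``.
    An ancestral call matching neither REF nor ALT is unresolvable.
    """
    for allele, source in ((ape_call, "from_apes"), (macaque_allele, "from_macaque")):
        if allele in (None, "", ".", "N"):
            continue
        if allele in (ref, alt):
            return allele, source
        return None, "unresolvable"
    return None, "unknown"


def _gt_alleles(gt: str) -> tuple[int, int] | None:
    """Parse '0/1'-style genotype into allele indices; None if missing."""
    if gt in MISSING_GT:
        return None
    sep = "/" if "/" in gt else "|"
    a, b = gt.split(sep)
    if a == "." or b == ".":
        return None
    return int(a), int(b)


def archaic_condition(
    genotypes: dict[str, str],
    reliable: dict[str, bool],
    ancestral_index: int,
    het_neanderthal_is_derived: bool = True,
    het_is_ancestral: bool = False,
) -> bool:
    """Ancestrality condition relative to the three archaic individuals.

    Parameters
    ----------
    genotypes
        Mapping archaic -> genotype string ('0/0', '0/1', '1/1', './.').
    reliable
        Mapping archaic -> coverage reliability. A genotype that is missing
        or unreliable carries no information.
    ancestral_index
        0 if REF is ancestral, 1 if ALT is ancestral.
    het_neanderthal_is_derived
        Whether a heterozygous Neanderthal counts as "carrying the derived
        allele" in the gene-flow clause (default True).
    het_is_ancestral
        Whether a heterozygous archaic satisfies "has the ancestral allele"
        in the all-ancestral clause (strict default: False, homozygous
        ancestral required).

    Raises
    ------
    ValueError
        If no archaic genotype is both present and reliable (undecidable).
    """
    derived_index = 1 - ancestral_index
    parsed = {}
    for name in ARCHAICS:
        alleles = _gt_alleles(genotypes.get(name, "./."))
        parsed[name] = alleles if (alleles is not None and reliable.get(name, False)) else None
    if all(v is None for v in parsed.values()):
        raise ValueError("no reliable archaic genotype: condition undecidable")

    def is_ancestral(alleles: tuple[int, int]) -> bool:
        if het_is_ancestral:
            return ancestral_index in alleles
        return alleles == (ancestral_index, ancestral_index)

    # Clause 1: every informative archaic has the ancestral allele.
    clause1 = all(is_ancestral(v) for v in parsed.values() if v is not None)

    # Clause 2: Denisovan homozygous ancestral, >=1 Neanderthal carries derived.
    clause2 = False
    den = parsed["denisova"]
    if den is not None and den == (ancestral_index, ancestral_index):
        for nea in NEANDERTHALS:
            v = parsed[nea]
            if v is None:
                continue
            if v == (derived_index, derived_index):
                clause2 = True
            elif derived_index in v and het_neanderthal_is_derived:
                clause2 = True
    return clause1 or clause2


@dataclass
class ClassifiedVariant:
    """Classification flags for one catalog variant."""

    rsid: str | None
    passes_coverage: bool
    ancestral_resolved: bool
    derived_major: bool
    hf_global: bool
    hf_all_metapops: bool
    archaic_cond: bool
    is_derived_hf: bool
    has_rsid: bool
    exclusion_reason: str | None = None


def classify_record(
    row: pd.Series | dict,
    threshold: float = 0.90,
    stringent_metapop: bool = True,
    het_neanderthal_is_derived: bool = True,
    het_is_ancestral: bool = False,
) -> ClassifiedVariant:
    """Classify one catalog row (see module docstring for the rule set).

    ``row`` uses the catalog dialect: ``ref``, ``alt``, ``af_global``,
    ``af_AFR`` … ``af_SAS`` (ALT-allele frequencies), ``ancestral_allele``,
    ``ancestral_call``, ``gt_altai``/``gt_vindija``/``gt_denisova``,
    ``dp_altai``/``dp_vindija``/``dp_denisova``, optional ``rsid``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"frequency threshold must be in (0.5, 1], got {threshold}")

    rsid = row.get("rsid") if isinstance(row, dict) else row.get("rsid", None)
    if rsid is not None and (rsid == "." or rsid == "" or (isinstance(rsid, float) and np.isnan(rsid))):
        rsid = None
    has_rsid = rsid is not None

    cov = coverage_pass(row.get("dp_altai"), row.get("dp_vindija"), row.get("dp_denisova"))

    anc_allele = row.get("ancestral_allele")
    if anc_allele in ("", ".", None) or (isinstance(anc_allele, float) and np.isnan(anc_allele)):
        anc_allele = None
    resolved = anc_allele in (row["ref"], row["alt"])

    def excluded(reason: str) -> ClassifiedVariant:
        return ClassifiedVariant(
            rsid=rsid, passes_coverage=cov["any"], ancestral_resolved=resolved,
            derived_major=False, hf_global=False, hf_all_metapops=False,
            archaic_cond=False, is_derived_hf=False, has_rsid=has_rsid,
            exclusion_reason=reason,
        )

    if not resolved:
        return excluded("ancestral_unresolved")

    ancestral_index = 0 if anc_allele == row["ref"] else 1
    af_alt = float(row["af_global"])
    af_derived = af_alt if ancestral_index == 0 else 1.0 - af_alt

    derived_major = af_derived > 0.5  # ties at 0.50 fail the major-allele test
    hf_global = af_derived >= threshold
    metapop_derived = []
    for mp in METAPOPS:
        f = float(row[f"af_{mp}"])
        metapop_derived.append(f if ancestral_index == 0 else 1.0 - f)
    hf_all_metapops = all(f >= threshold for f in metapop_derived)

    genotypes = {a: row.get(f"gt_{a}", "./.") for a in ARCHAICS}
    reliable = {a: cov[a] for a in ARCHAICS}
    try:
        arch = archaic_condition(
            genotypes, reliable, ancestral_index,
            het_neanderthal_is_derived=het_neanderthal_is_derived,
            het_is_ancestral=het_is_ancestral,
        )
    except ValueError:
        return excluded("no_reliable_archaic")

    is_hf = (
        derived_major
        and hf_global
        and (hf_all_metapops or not stringent_metapop)
        and arch
    )
    return ClassifiedVariant(
        rsid=rsid, passes_coverage=cov["any"], ancestral_resolved=True,
        derived_major=derived_major, hf_global=hf_global,
        hf_all_metapops=hf_all_metapops, archaic_cond=arch,
        is_derived_hf=is_hf, has_rsid=has_rsid, exclusion_reason=None,
    )


def classify_catalog(
    catalog: pd.DataFrame,
    threshold: float = 0.90,
    stringent_metapop: bool = True,
    het_neanderthal_is_derived: bool = True,
    het_is_ancestral: bool = False,
) -> pd.DataFrame:
    """Classify every catalog row; returns the catalog with flag columns added."""
    flags = [
        classify_record(
            row, threshold=threshold, stringent_metapop=stringent_metapop,
            het_neanderthal_is_derived=het_neanderthal_is_derived,
            het_is_ancestral=het_is_ancestral,
        )
        for _, row in catalog.iterrows()
    ]
    out = catalog.copy()
    for col in (
        "passes_coverage", "ancestral_resolved", "derived_major", "hf_global",
        "hf_all_metapops", "archaic_cond", "is_derived_hf", "has_rsid",
        "exclusion_reason",
    ):
        out[col] = [getattr(f, col) for f in flags]
    return out


def drop_unmapped(classified: pd.DataFrame) -> pd.DataFrame:
    """Prune variants without an assigned rsID (required to map onto eQTL tables)."""
    keep = classified["has_rsid"] if "has_rsid" in classified else classified["rsid"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped == len(classified) and len(classified) > 0:
        logger.warning("all %d variants lack rsIDs; returning empty set", n_dropped)
    elif n_dropped:
        logger.info("dropped %d variant(s) without rsIDs", n_dropped)
    return classified.loc[keep].reset_index(drop=True)
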