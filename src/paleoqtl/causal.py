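"""Two-sample Mendelian randomization and Bayesian colocalization.

Instruments are the top eQTL variant per gene x tissue (smallest nominal p,
kept at p <= 5e-4 and required to be present in the derived-allele
catalog). After allele harmonization against the outcome GWAS, the causal
effect of expression on the outcome is estimated by the single-instrument
Wald ratio

    beta_IV = beta_outcome / beta_exposure,
    se_IV   = |se_outcome / beta_exposure|        (first-order delta),

with a two-sided normal p-value and Bonferroni correction over the family
of gene x trait tests run together.

Colocalization uses Wakefield approximate Bayes factors per variant and
trait,

    log ABF = 1/2 [ log(V/(V+W)) + z² W/(V+W) ],   V = se², z = beta/se,

with prior effect variance W = sd_prior² (0.15 for quantitative traits),
combined into the standard five-hypothesis posterior (H0: no association;
H1/H2: one trait only; H3: two distinct causal variants; H4: one shared
causal variant) with priors p1, p2, p12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult", "ColocResult", "select_instruments", "harmonize",
    "wald_ratio", "bonferroni", "coloc_abf",
]

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def select_instruments(
    eqtls: pd.DataFrame,
    derived_catalog_ids: set,
    p_threshold: float = 5e-4,
) -> pd.DataFrame:
    """Top eQTL variant per gene x tissue, thresholded and catalog-filtered.

    The derived-allele catalog membership is deliberately *not* restricted
    to high-frequency variants: pleiotropy and LD can masquerade as
    causality for a nearly fixed variant merely linked to the true causal
    one, so the instrument pool keeps all derived variants.

    Ties in p are broken by genomic position, ascending, for determinism.
    """
    df = eqtls.loc[eqtls["rsid"].notna() & eqtls["rsid"].isin(derived_catalog_ids)]
    df = df.sort_values(["pval_nominal", "chrom", "pos"], kind="mergesort")
    top = df.groupby(["gene_id", "tissue"], as_index=False).first()
    return top.loc[top["pval_nominal"] <= p_threshold].reset_index(drop=True)


def harmonize(instrument: pd.Series | dict, gwas_row: pd.Series | dict,
              palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)) -> dict | None:
    """Align a GWAS record to the instrument's effect allele.

    The instrument's effect allele is its ALT allele (eQTL slopes are
    ALT-dosage effects). If the GWAS effect allele is the instrument's
    other allele, the GWAS beta sign and EAF are flipped. Palindromic
    variants (A/T or C/G) with EAF inside the ambiguity window are dropped
    (returns None), as are records with incompatible allele sets.
    """
    ea, oa = gwas_row["effect_allele"], gwas_row["other_allele"]
    ref, alt = instrument["ref"], instrument["alt"]
    if {ea, oa} != {ref, alt}:
        logger.info("allele sets incompatible for %s; dropped", gwas_row.get("SNP"))
        return None
    if frozenset((ea, oa)) in PALINDROMIC:
        lo, hi = palindromic_eaf_window
        if lo <= float(gwas_row["eaf"]) <= hi:
            logger.info("palindromic variant %s with ambiguous EAF; dropped",
                        gwas_row.get("SNP"))
            return None
    flip = ea != alt
    return {
        "beta_exposure": float(instrument["slope"]),
        "se_exposure": float(instrument["slope_se"]),
        "beta_outcome": -float(gwas_row["beta"]) if flip else float(gwas_row["beta"]),
        "se_outcome": float(gwas_row["se"]),
    }


@dataclass
class MRResult:
    """Wald-ratio MR estimate for one gene x tissue x trait triple."""

    gene: str
    tissue: str
    trait: str
    instrument: str
    beta: float
    se: float
    pvalue: float
    pvalue_adjusted: float | None = None


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float) -> tuple[float, float, float]:
    """Single-instrument Wald ratio: (beta_IV, se_IV, two-sided p)."""
    if beta_exposure == 0:
        raise ValueError("Wald ratio undefined for zero exposure effect")
    beta_iv = beta_outcome / beta_exposure
    se_iv = abs(se_outcome / beta_exposure)
    p = 2 * stats.norm.sf(abs(beta_iv / se_iv)) if se_iv > 0 else float("nan")
    return float(beta_iv), float(se_iv), float(p)


def bonferroni(results: list[MRResult]) -> list[MRResult]:
    """Adjust p over the family of all tests run in one invocation."""
    m = len(results)
    for r in results:
        r.pvalue_adjusted = min(1.0, r.pvalue * m)
    return results


def run_mr(
    instruments: pd.DataFrame,
    gwas: pd.DataFrame,
    trait: str | None = None,
) -> list[MRResult]:
    """Harmonize each instrument against a GWAS table and run Wald ratios.

    ``gwas`` follows the summary dialect (SNP, beta, se, effect_allele,
    other_allele, eaf, trait). Returns Bonferroni-adjusted results over all
    triples tested here.
    """
    gw = gwas.set_index("SNP")
    gw = gw[~gw.index.duplicated()]
    trait_label = trait or (str(gwas["trait"].iloc[0]) if "trait" in gwas else "trait")
    results = []
    for _, inst in instruments.iterrows():
        if inst["rsid"] not in gw.index:
            continue
        aligned = harmonize(inst, gw.loc[inst["rsid"]])
        if aligned is None or aligned["beta_exposure"] == 0:
            continue
        b, s, p = wald_ratio(**aligned)
        results.append(MRResult(gene=inst["gene_id"], tissue=inst["tissue"],
                                trait=trait_label, instrument=inst["rsid"],
                                beta=b, se=s, pvalue=p))
    return bonferroni(results)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict  # {"PP0": ..., ..., "PP4": ...}
    priors: tuple  # (p1, p2, p12)
    n_variants: int
    labf_trait1: np.ndarray
    labf_trait2: np.ndarray

    def __getitem__(self, key: str) -> float:
        return self.pp[key]


def _wakefield_labf(beta: np.ndarray, se: np.ndarray, sd_prior: float) -> np.ndarray:
    v = se ** 2
    if np.any(v <= 0):
        raise ValueError("standard errors must be positive")
    z2 = (beta / se) ** 2
    r = sd_prior ** 2 / (sd_prior ** 2 + v)
    return 0.5 * (np.log(1 - r) + z2 * r)


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    sd_prior1: float = 0.15,
    sd_prior2: float = 0.15,
) -> ColocResult:
    """Approximate-Bayes-factor colocalization on one region.

    Each trait DataFrame needs ``rsid``, ``beta``, ``se``; variants are
    matched on rsid and rows with missing or non-positive se are dropped.
    ``sd_prior*`` is the prior standard deviation of the (standardised)
    effect for each trait (0.15 is the quantitative-trait convention).
    Posteriors are normalized to sum to one.
    """
    t1 = trait1.dropna(subset=["beta", "se"]).loc[lambda d: d["se"] > 0]
    t2 = trait2.dropna(subset=["beta", "se"]).loc[lambda d: d["se"] > 0]
    merged = t1.merge(t2, on="rsid", suffixes=("_1", "_2"))
    n = len(merged)
    if n == 0:
        raise ValueError("no shared variants between the two traits in this region")
    if n == 1:
        logger.warning("single-variant region: H3 is unidentifiable")

    l1 = _wakefield_labf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), sd_prior1)
    l2 = _wakefield_labf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), sd_prior2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    # sum over ordered distinct pairs: sum_i sum_{j != i} = sum_i BF1_i * (S2 - BF2_i)
    cross = lsum1 + lsum2
    if n > 1:
        # log( exp(cross) - exp(lsum12) ), guarded against cancellation
        diff = cross + np.log1p(-np.exp(np.minimum(lsum12 - cross, -1e-12)))
    else:
        diff = -np.inf
    lh3 = np.log(p1) + np.log(p2) + diff
    lh4 = np.log(p12) + lsum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(
        pp={f"PP{i}": float(pp[i]) for i in range(5)},
        priors=(p1, p2, p12), n_variants=n,
        labf_trait1=l1, labf_trait2=l2,
    )
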