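"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the data the pipeline consumes in
real mode: a variant catalog with modern metapopulation frequencies and
three archaic diploid genotypes with per-site coverage; ape/macaque
ancestral calls; an LD-structured haplotype panel; tissue-stratified
cis-eQTL tables with slopes, nominal p-values and FDR flags; selective-sweep
window sets from two "studies"; and GWAS summary statistics with
configurable shared/distinct causal variants.

Haplotypes follow a Markov template-copying model: each haplotype copies one
of ``n_templates`` founder haplotypes and switches template between adjacent
variants with probability ``1 − exp(−d/L)`` for inter-variant distance ``d``
and copy length ``L``. Variants are laid out in dense per-gene blocks, so LD
is strong within a cis-window and negligible between genes — enough
structure for clumping and colocalization to be meaningfully exercised,
without a full coalescent simulation.

Ground-truth labels are consistent with the classifier's rules *by
construction*: variants labelled derived-HF are built to satisfy every rule
(frequency forced to >= 0.92 in the panel, all metapopulations >= the
threshold, archaic genotypes drawn from one of the two qualifying
configurations), and every other variant has at least one rule explicitly
broken (derived allele set to the minor allele, a Denisovan homozygous
derived genotype, failed archaic coverage, an unresolved ancestral state, or
— for the stringent filter specifically — one metapopulation below
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ld import HaplotypePanel
from .sweep_overlap import GenomicWindow, count_overlaps, merge_windows
from .variant_filter import METAPOPS

__all__ = [
    "SimConfig", "GroundTruth", "SimData", "TISSUE_SAMPLES", "DUPLICATE_TISSUE_PAIRS",
    "CONSEQUENCE_PROBS", "gen_haplotypes", "gen_variant_catalog", "gen_eqtl_tables",
    "gen_sweep_windows", "gen_gwas_summary", "simulate",
]

#: The 15 central-nervous-system-related tissues with RNA-seq sample sizes
#: in the range of the real per-tissue sample counts.
TISSUE_SAMPLES = {
    "Adrenal Gland": 233,
    "Amygdala": 129,
    "Anterior cingulate cortex (BA24)": 147,
    "Caudate": 194,
    "Cerebellar Hemisphere": 175,
    "Cerebellum": 209,
    "Cortex": 205,
    "Frontal Cortex (BA9)": 176,
    "Hippocampus": 165,
    "Hypothalamus": 170,
    "Nucleus accumbens": 202,
    "Pituitary": 237,
    "Putamen": 153,
    "Spinal cord": 126,
    "Substantia nigra": 114,
}

#: Re-sampled tissue pairs whose eQTL effects are generated highly correlated.
DUPLICATE_TISSUE_PAIRS = [
    ("Cerebellum", "Cerebellar Hemisphere"),
    ("Cortex", "Frontal Cortex (BA9)"),
]

#: Consequence-category sampling probabilities (order fixed for determinism).
CONSEQUENCE_PROBS = {
    "intron": 0.44,
    "intergenic": 0.20,
    "3'UTR": 0.08,
    "synonymous": 0.07,
    "missense": 0.06,
    "5'UTR": 0.06,
    "non-coding transcript": 0.06,
    "NMD transcript": 0.03,
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """All simulation knobs; identical config (incl. seed) gives identical output."""

    n_variants: int = 2000
    n_haplotypes: int = 400
    n_tissues: int = 15
    metapop_names: tuple = METAPOPS
    hf_fraction: float = 0.15
    sweep_window_count: int = 40
    sweep_enrichment_factor: float = 1.0
    coloc_scenario: str = "H4"
    seed: int = 0

    # genome / LD layout
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 32_000_000,
                                 "chr3": 26_000_000, "chr4": 22_000_000}
    )
    variants_per_gene: int = 20
    copy_length_bp: float = 25_000.0
    n_templates: int = 8
    switch_prob: float | None = None  # fixed per-site switch prob (overrides distance model)

    # catalog composition
    coverage_fail_fraction: float = 0.04
    missing_rsid_fraction: float = 0.03
    unknown_ancestral_fraction: float = 0.02
    metapop_only_fail_fraction: float = 0.05  # non-HF that fail only the stringent filter

    # eQTL generation
    eqtl_gene_fraction: float = 0.4
    hf_causal_weight: float = 0.6
    base_tissue_activity: float = 0.7
    tissue_enrichment: dict = field(default_factory=dict)
    category_enrichment: dict = field(default_factory=dict)
    eqtl_noise_sd: float = 1.0

    # sweeps
    sweep_coverage: tuple = (0.05, 0.10)  # genome fraction per source

    # GWAS
    gwas_n: int = 30_000
    mr_true_ratio: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_variants", "n_haplotypes", "n_tissues", "sweep_window_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.hf_fraction <= 1.0:
            raise ValueError("hf_fraction must be in [0, 1]")
        if self.sweep_enrichment_factor < 1.0:
            raise ValueError("sweep_enrichment_factor must be >= 1")
        if self.coloc_scenario not in {"H0", "H1", "H2", "H3", "H4"}:
            raise ValueError(f"unknown coloc scenario {self.coloc_scenario!r}")
        if self.n_tissues > len(TISSUE_SAMPLES):
            raise ValueError(f"at most {len(TISSUE_SAMPLES)} tissues available")

    @property
    def tissues(self) -> list[str]:
        return list(TISSUE_SAMPLES)[: self.n_tissues]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class GroundTruth:
    """Per-variant and per-gene labels backing every downstream assertion.

    ``variants`` columns: rsid, gene_id, is_derived_hf, derived_allele,
    break_reason (the rule deliberately broken; None for derived-HF rows),
    in_sweep_<source>.
    ``genes`` columns: gene_id, is_eqtl_gene, causal_rsid, base_effect,
    gwas_scenario, gwas_causal_rsid, gwas_effect.
    ``effects``: tissue x gene true effect matrix.
    """

    variants: pd.DataFrame
    genes: pd.DataFrame | None = None
    effects: pd.DataFrame | None = None


@dataclass
class SimData:
    """Bundle of everything :func:`simulate` produces."""

    config: SimConfig
    panel: HaplotypePanel
    catalog: pd.DataFrame
    truth: GroundTruth
    eqtls: pd.DataFrame | None = None
    sample_sizes: pd.Series | None = None
    windows: list | None = None
    gwas: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# haplotypes


def _variant_layout(cfg: SimConfig, rng: np.random.Generator):
    """Place variants in dense per-gene blocks across the synthetic genome."""
    n_genes = max(1, cfg.n_variants // cfg.variants_per_gene)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    gene_chrom_idx = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())

    per_gene = np.full(n_genes, cfg.n_variants // n_genes)
    per_gene[: cfg.n_variants - per_gene.sum()] += 1

    chrom_col, pos_col, gene_col = [], [], []
    for g in range(n_genes):
        c = chroms[gene_chrom_idx[g]]
        span = int(per_gene[g] * 2_500 + 10_000)
        start = int(rng.integers(1, cfg.chrom_lengths[c] - span))
        gaps = rng.integers(200, 2_500, size=per_gene[g])
        positions = start + np.cumsum(gaps)
        chrom_col.extend([c] * per_gene[g])
        pos_col.extend(positions.tolist())
        gene_col.extend([f"GENE{g:04d}"] * per_gene[g])

    df = pd.DataFrame({"chrom": chrom_col, "pos": pos_col, "gene_id": gene_col})
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["vid"] = [f"rs{900000 + i}" for i in range(len(df))]
    return df


def gen_haplotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Markov template-copying haplotype panel over the block layout."""
    rng = rng or cfg.rng(0)
    layout = _variant_layout(cfg, rng)
    n, m = cfg.n_haplotypes, len(layout)

    target_f = rng.uniform(0.05, 0.95, size=m)
    templates = (rng.random((cfg.n_templates, m)) < target_f).astype(np.uint8)

    matrix = np.empty((n, m), dtype=np.uint8)
    state = rng.integers(0, cfg.n_templates, size=n)
    prev_chrom, prev_pos = None, 0
    for j in range(m):
        c, p = layout.at[j, "chrom"], layout.at[j, "pos"]
        if c != prev_chrom:
            state = rng.integers(0, cfg.n_templates, size=n)
        else:
            if cfg.switch_prob is not None:
                p_switch = cfg.switch_prob
            else:
                p_switch = 1.0 - np.exp(-(p - prev_pos) / cfg.copy_length_bp)
            mask = rng.random(n) < p_switch
            if mask.any():
                state[mask] = rng.integers(0, cfg.n_templates, size=int(mask.sum()))
        matrix[:, j] = templates[state, j]
        prev_chrom, prev_pos = c, p

    panel = HaplotypePanel(
        matrix=matrix,
        chrom=layout["chrom"].to_numpy(),
        pos=layout["pos"].to_numpy(),
        ids=layout["vid"].to_numpy(),
    )
    panel.gene_id = layout["gene_id"].to_numpy()  # carried for catalog/eQTL stages
    return panel


# ---------------------------------------------------------------------------
# variant catalog


def _draw_consequences(cfg, rng, n, enriched: bool) -> np.ndarray:
    cats = list(CONSEQUENCE_PROBS)
    probs = np.array([CONSEQUENCE_PROBS[c] for c in cats])
    if enriched and cfg.category_enrichment:
        probs = probs * np.array([cfg.category_enrichment.get(c, 1.0) for c in cats])
    probs = probs / probs.sum()
    return rng.choice(cats, size=n, p=probs)


def _force_column(panel, j, derived_is_alt, f_derived, rng):
    """Overwrite a panel column so the derived allele is nearly fixed."""
    n = panel.n_haplotypes
    m_anc = int(round((1 - f_derived) * n))
    m_anc = min(max(m_anc, 1), int(np.floor(0.08 * n)))  # keep realized freq >= 0.92
    col = np.full(n, 1 if derived_is_alt else 0, dtype=np.uint8)
    anc_rows = rng.choice(n, size=m_anc, replace=False)
    col[anc_rows] = 0 if derived_is_alt else 1
    panel.matrix[:, j] = col


def _archaic_block_hf(rng, threshold_ok=True):
    """Archaic genotypes/coverages satisfying the ancestrality condition.

    Ancestral allele is genotype index 0 by convention here; caller remaps.
    """
    if rng.random() < 0.7:  # clause 1: all reliable archaics homozygous ancestral
        gts = ["0/0", "0/0", "0/0"]
        # occasionally mask one Neanderthal via out-of-bounds coverage
        dps = [int(rng.integers(5, 106)), int(rng.integers(5, 76)), int(rng.integers(5, 76))]
        if rng.random() < 0.2:
            k = int(rng.integers(0, 2))
            dps[k] = int(rng.choice([2, 150]))
    else:  # clause 2: Denisovan ancestral, one Neanderthal carries derived
        nea = int(rng.integers(0, 2))
        gts = ["0/0", "0/0", "0/0"]
        gts[nea] = str(rng.choice(["0/1", "1/1"]))
        dps = [int(rng.integers(5, 106)), int(rng.integers(5, 76)), int(rng.integers(5, 76))]
    return gts, dps


def _remap_gt(gt: str, ancestral_index: int) -> str:
    """Remap an ancestral(0)/derived(1) genotype to REF/ALT indices."""
    if ancestral_index == 0:
        return gt
    return gt.replace("0", "x").replace("1", "0").replace("x", "1")


def gen_variant_catalog(
    cfg: SimConfig, panel: HaplotypePanel, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the variant catalog and its ground truth over a panel.

    Note: the panel's columns for variants designated derived-HF are
    overwritten in place so their panel frequency genuinely is nearly fixed
    (the frequency-consistency invariant is exact, not approximate).
    """
    rng = rng or cfg.rng(1)
    m = panel.n_variants
    n_hf = int(round(cfg.hf_fraction * m))
    hf_idx = set(rng.choice(m, size=n_hf, replace=False).tolist()) if n_hf else set()

    gene_ids = getattr(panel, "gene_id", np.array([f"GENE{i // cfg.variants_per_gene:04d}"
                                                   for i in range(m)]))

    rows, truth_rows = [], []
    negbin_p = 0.5
    for j in range(m):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref, alt = _BASES[ref], _BASES[alt]
        is_hf = j in hf_idx
        break_reason = None

        if is_hf:
            derived_is_alt = bool(rng.random() < 0.5)
            f_derived = float(rng.uniform(0.93, 0.995))
            _force_column(panel, j, derived_is_alt, f_derived, rng)
            f_alt = float(panel.matrix[:, j].mean())
            f_der = f_alt if derived_is_alt else 1 - f_alt
            mp_der = rng.uniform(max(0.90, f_der - 0.04), min(1.0, f_der + 0.02),
                                 size=len(cfg.metapop_names))
            anc_allele = ref if derived_is_alt else alt
            anc_call = "from_apes" if rng.random() < 0.85 else "from_macaque"
            gts, dps = _archaic_block_hf(rng)
            anc_index = 0 if anc_allele == ref else 1
            gts = [_remap_gt(g, anc_index) for g in gts]
            rsid = panel.ids[j]
        else:
            f_alt = float(panel.matrix[:, j].mean())
            u = rng.random()
            anc_call = "from_apes" if rng.random() < 0.85 else "from_macaque"
            gts = None
            if u < cfg.unknown_ancestral_fraction:
                break_reason = "ancestral_unknown"
                anc_allele, anc_call = None, "unknown"
            elif u < cfg.unknown_ancestral_fraction + cfg.coverage_fail_fraction:
                break_reason = "coverage_fail"
                anc_allele = ref if rng.random() < 0.5 else alt
            elif u < (cfg.unknown_ancestral_fraction + cfg.coverage_fail_fraction
                      + cfg.metapop_only_fail_fraction):
                # passes every global rule but one metapopulation dips below 0.90
                break_reason = "metapop_below_threshold"
                derived_is_alt = bool(rng.random() < 0.5)
                _force_column(panel, j, derived_is_alt, float(rng.uniform(0.93, 0.99)), rng)
                f_alt = float(panel.matrix[:, j].mean())
                anc_allele = ref if derived_is_alt else alt
            else:
                anc_allele = ref if rng.random() < 0.5 else alt
                derived_is_alt = anc_allele == ref
                f_der = f_alt if derived_is_alt else 1 - f_alt
                if f_der >= 0.90:
                    if rng.random() < 0.5:
                        break_reason = "ancestral_is_major"
                        anc_allele = alt if derived_is_alt else ref
                    else:
                        break_reason = "denisovan_derived"
                else:
                    break_reason = "low_frequency"

            derived_is_alt = anc_allele != alt if anc_allele is not None else True
            f_der = f_alt if derived_is_alt else 1 - f_alt
            if break_reason == "metapop_below_threshold":
                mp_der = rng.uniform(0.90, min(1.0, f_der + 0.02), size=len(cfg.metapop_names))
                mp_der[rng.integers(0, len(cfg.metapop_names))] = rng.uniform(0.70, 0.88)
            else:
                mp_der = np.clip(f_der + rng.uniform(-0.05, 0.05, size=len(cfg.metapop_names)),
                                 0.0, 1.0)

            anc_index = 0 if anc_allele == ref else (1 if anc_allele == alt else 0)
            if break_reason == "coverage_fail":
                gts = ["0/0", "0/0", "0/0"]
                dps = [int(rng.choice([0, 2, 140])), int(rng.choice([0, 3, 90])),
                       int(rng.choice([1, 4, 80]))]
            elif break_reason == "metapop_below_threshold":
                # archaic condition must hold so only the stringent filter fails
                gts, dps = _archaic_block_hf(rng)
                gts = [_remap_gt(g, anc_index) for g in gts]
            elif break_reason == "denisovan_derived":
                gts = [_remap_gt("0/0", anc_index), _remap_gt("0/0", anc_index),
                       _remap_gt("1/1", anc_index)]
                dps = [int(rng.integers(5, 106)), int(rng.integers(5, 76)),
                       int(rng.integers(5, 76))]
            else:
                # archaic state irrelevant to the label; draw loosely
                draw = lambda: str(rng.choice(["0/0", "0/0", "0/1", "1/1", "./."],
                                              p=[0.5, 0.2, 0.15, 0.1, 0.05]))
                gts = [_remap_gt(draw(), anc_index) for _ in range(3)]
                dps = [int(np.clip(rng.negative_binomial(30, negbin_p) + 5, 0, 200))
                       for _ in range(3)]
            rsid = panel.ids[j] if rng.random() >= cfg.missing_rsid_fraction else None

        # metapop frequencies are stored ALT-oriented, like the global one
        derived_is_alt_final = (anc_allele == ref) if anc_allele is not None else True
        mp_alt = mp_der if derived_is_alt_final else 1.0 - mp_der

        row = {
            "chrom": panel.chrom[j], "pos": int(panel.pos[j]), "rsid": rsid,
            "ref": ref, "alt": alt,
            "ancestral_call": anc_call,
            "ancestral_allele": anc_allele if anc_allele is not None else ".",
            "af_global": float(panel.matrix[:, j].mean()),
            "gene_id": gene_ids[j],
        }
        for k, mp in enumerate(cfg.metapop_names):
            row[f"af_{mp}"] = float(mp_alt[k])
        for k, a in enumerate(("altai", "vindija", "denisova")):
            row[f"gt_{a}"] = gts[k]
            row[f"dp_{a}"] = dps[k]
        rows.append(row)
        truth_rows.append({
            "vid": panel.ids[j], "rsid": rsid, "gene_id": gene_ids[j],
            "chrom": panel.chrom[j], "pos": int(panel.pos[j]),
            "is_derived_hf": is_hf,
            "derived_allele": (alt if (anc_allele == ref) else ref) if anc_allele else None,
            "break_reason": break_reason,
        })

    catalog = pd.DataFrame(rows)
    catalog["consequence"] = _draw_consequences(cfg, rng, m, enriched=False)
    if cfg.category_enrichment and hf_idx:
        hf_list = sorted(hf_idx)
        catalog.loc[hf_list, "consequence"] = _draw_consequences(
            cfg, rng, len(hf_list), enriched=True
        )
    truth = GroundTruth(variants=pd.DataFrame(truth_rows))
    return catalog, truth


# ---------------------------------------------------------------------------
# eQTL tables


def gen_eqtl_tables(
    cfg: SimConfig,
    catalog: pd.DataFrame,
    panel: HaplotypePanel,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-tissue significant cis-eQTL style tables with FDR flags.

    For an eQTL gene, one causal variant per gene (preferring derived-HF
    variants with probability ``hf_causal_weight``) drives marginal slopes
    through LD: the observed slope of variant v is
    ``b_gt * corr(v, causal) + noise`` with standard error shrinking in the
    tissue sample size, so eQTL discovery counts naturally track sample size.
    Duplicate tissue pairs share effects with small perturbations.
    """
    rng = rng or cfg.rng(2)
    tissues = cfg.tissues
    sample_sizes = pd.Series({t: TISSUE_SAMPLES[t] for t in tissues}, name="n_samples")
    hf_set = set(truth.variants.loc[truth.variants["is_derived_hf"], "vid"])

    freqs = panel.allele_freq()
    gene_ids = getattr(panel, "gene_id")
    genes = pd.unique(gene_ids)

    dup_follower = {b: a for a, b in DUPLICATE_TISSUE_PAIRS}

    gene_rows, effect_rows = [], {}
    records = {"vid": [], "gene_id": [], "tissue": [], "slope": [], "slope_se": [],
               "pval_nominal": []}
    for g in genes:
        idx = np.flatnonzero(gene_ids == g)
        maf_ok = idx[(freqs[idx] >= 0.02) & (freqs[idx] <= 0.98)]
        is_eqtl = bool(rng.random() < cfg.eqtl_gene_fraction) and len(maf_ok) > 0
        causal_j, base_effect = None, 0.0
        if is_eqtl:
            hf_in_gene = [j for j in maf_ok if panel.ids[j] in hf_set]
            if hf_in_gene and rng.random() < cfg.hf_causal_weight:
                causal_j = int(rng.choice(hf_in_gene))
            else:
                causal_j = int(rng.choice(maf_ok))
            base_effect = float(rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0]))

        # tissue activity: all tissues, or a small subset
        causal_is_hf = causal_j is not None and panel.ids[causal_j] in hf_set
        active = {}
        for t in tissues:
            if t in dup_follower and dup_follower[t] in active:
                active[t] = active[dup_follower[t]]
                continue
            p_act = cfg.base_tissue_activity
            if causal_is_hf:
                p_act = min(1.0, p_act * cfg.tissue_enrichment.get(t, 1.0))
            active[t] = is_eqtl and (rng.random() < p_act)

        effects_t = {}
        for t in tissues:
            if not active[t]:
                effects_t[t] = 0.0
            elif t in dup_follower and dup_follower[t] in effects_t:
                effects_t[t] = effects_t[dup_follower[t]] + float(rng.normal(0, 0.05))
            else:
                effects_t[t] = base_effect * float(rng.normal(1.0, 0.15))
        effect_rows[g] = effects_t
        gene_rows.append({
            "gene_id": g, "is_eqtl_gene": is_eqtl,
            "causal_vid": panel.ids[causal_j] if causal_j is not None else None,
            "base_effect": base_effect,
        })

        if len(idx) == 0:
            continue
        r_to_causal = {}
        if causal_j is not None:
            causal_col = panel.matrix[:, causal_j].astype(float)
            cc = causal_col - causal_col.mean()
            denom = np.sqrt((cc ** 2).sum())
            for j in idx:
                col = panel.matrix[:, j].astype(float)
                c2 = col - col.mean()
                d2 = np.sqrt((c2 ** 2).sum())
                r_to_causal[j] = float(cc @ c2 / (denom * d2)) if d2 > 0 else 0.0
        for t in tissues:
            n_t = sample_sizes[t]
            b_gt = effects_t[t]
            for j in idx:
                f = freqs[j]
                if f <= 0 or f >= 1:
                    continue
                se = cfg.eqtl_noise_sd / np.sqrt(2 * f * (1 - f) * n_t)
                mean_beta = b_gt * r_to_causal.get(j, 0.0) if causal_j is not None else 0.0
                beta_hat = mean_beta + float(rng.normal(0, se))
                z = beta_hat / se
                p = 2 * stats.norm.sf(abs(z))
                records["vid"].append(panel.ids[j])
                records["gene_id"].append(g)
                records["tissue"].append(t)
                records["slope"].append(beta_hat)
                records["slope_se"].append(se)
                records["pval_nominal"].append(max(p, 5e-324))

    eqtls = pd.DataFrame(records)
    # FDR flag per tissue (Benjamini-Hochberg), emulating per-tissue q-values
    from statsmodels.stats.multitest import multipletests

    flags = np.zeros(len(eqtls), dtype=bool)
    for t in tissues:
        mask = (eqtls["tissue"] == t).to_numpy()
        if mask.any():
            flags[mask] = multipletests(eqtls.loc[mask, "pval_nominal"], alpha=0.05,
                                        method="fdr_bh")[0]
    eqtls["qval_pass"] = flags

    # join rsid + consequence from the catalog (vid == panel id; rsid may be missing)
    cat = catalog.copy()
    cat["vid"] = panel.ids
    eqtls = eqtls.merge(
        cat[["vid", "rsid", "chrom", "pos", "ref", "alt", "consequence"]],
        on="vid", how="left",
    )

    truth.genes = pd.DataFrame(gene_rows)
    truth.effects = pd.DataFrame(effect_rows).T.rename_axis("gene_id")
    return eqtls, sample_sizes


# ---------------------------------------------------------------------------
# sweep windows


def gen_sweep_windows(
    cfg: SimConfig,
    catalog: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    sources: tuple[str, str] = ("study1", "study2"),
) -> list[GenomicWindow]:
    """Two selective-sweep window sets with a controllable HF enrichment.

    With enrichment factor 1 every window start is uniform (the exact null
    for the permutation test). For factor e > 1, a fraction
    ``q = min(1, (e-1) * coverage * n_hf / n_windows)`` of windows is centred
    on randomly chosen derived-HF variant positions, which raises the
    expected in-window HF rate to about e times the background to first
    order.
    """
    rng = rng or cfg.rng(3)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    hf = truth.variants.loc[truth.variants["is_derived_hf"]]

    windows: list[GenomicWindow] = []
    for source, coverage in zip(sources, cfg.sweep_coverage):
        w = cfg.sweep_window_count
        wlen = int(coverage * total / w)
        if wlen >= lengths.min():
            raise ValueError("sweep window length exceeds the shortest chromosome")
        eps = cfg.sweep_enrichment_factor
        q = min(1.0, (eps - 1.0) * coverage * len(hf) / w) if len(hf) else 0.0
        for _ in range(w):
            if len(hf) and rng.random() < q:
                row = hf.iloc[int(rng.integers(0, len(hf)))]
                c, center = row["chrom"], int(row["pos"])
                start = int(np.clip(center - wlen // 2, 0, cfg.chrom_lengths[c] - wlen))
            else:
                ci = rng.choice(len(chroms), p=lengths / total)
                c = chroms[ci]
                start = int(rng.integers(0, cfg.chrom_lengths[c] - wlen))
            windows.append(GenomicWindow(chrom=c, start=start, end=start + wlen,
                                         source=source))

    # record in-sweep truth per source
    positions = truth.variants[["chrom", "pos"]]
    for source in sources:
        merged = merge_windows([w for w in windows if w.source == source])
        inside = count_overlaps(positions, merged, return_mask=True)
        truth.variants[f"in_sweep_{source}"] = inside
    return windows


# ---------------------------------------------------------------------------
# GWAS summaries


def gen_gwas_summary(
    cfg: SimConfig,
    catalog: pd.DataFrame,
    panel: HaplotypePanel,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    trait: str = "trait1",
    scenario: str | None = None,
) -> pd.DataFrame:
    """One trait's GWAS summary statistics under a colocalization scenario.

    H4: the GWAS causal variant in each eQTL gene's region is the eQTL
    causal variant itself, with effect ``mr_true_ratio x base_effect``.
    H3: a distinct causal variant in the same region (lowest |r| with the
    eQTL causal). H2: signals only in non-eQTL genes. H1/H0: GWAS null.
    Effect/other alleles are emitted with random REF/ALT orientation so
    harmonization is genuinely exercised.
    """
    rng = rng or cfg.rng(4)
    scenario = scenario or cfg.coloc_scenario
    if truth.genes is None:
        raise ValueError("generate eQTL tables before the GWAS summary")

    freqs = panel.allele_freq()
    gene_ids = getattr(panel, "gene_id")
    m = panel.n_variants
    mean_beta = np.zeros(m)

    gwas_rows = []
    for _, grow in truth.genes.iterrows():
        g = grow["gene_id"]
        idx = np.flatnonzero(gene_ids == g)
        poly = idx[(freqs[idx] > 0.01) & (freqs[idx] < 0.99)]
        if len(poly) == 0:
            continue
        causal_j, effect = None, 0.0
        if scenario == "H4" and grow["is_eqtl_gene"]:
            causal_j = int(panel.loc(grow["causal_vid"]))
            effect = cfg.mr_true_ratio * grow["base_effect"]
        elif scenario == "H3" and grow["is_eqtl_gene"]:
            eq_j = int(panel.loc(grow["causal_vid"]))
            eq_col = panel.matrix[:, eq_j].astype(float)
            best, best_r = None, np.inf
            for j in poly:
                if j == eq_j:
                    continue
                r = abs(np.corrcoef(eq_col, panel.matrix[:, j].astype(float))[0, 1])
                if r < best_r:
                    best, best_r = int(j), r
            causal_j = best
            effect = float(rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0]))
        elif scenario == "H2" and not grow["is_eqtl_gene"]:
            causal_j = int(rng.choice(poly))
            effect = float(rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0]))
        if causal_j is not None and effect != 0.0:
            cc = panel.matrix[:, causal_j].astype(float)
            cc = cc - cc.mean()
            dn = np.sqrt((cc ** 2).sum())
            for j in idx:
                col = panel.matrix[:, j].astype(float)
                c2 = col - col.mean()
                d2 = np.sqrt((c2 ** 2).sum())
                r = float(cc @ c2 / (dn * d2)) if d2 > 0 and dn > 0 else 0.0
                mean_beta[j] = effect * r
        gwas_rows.append({"gene_id": g, "gwas_causal_vid":
                          panel.ids[causal_j] if causal_j is not None else None,
                          "gwas_effect": effect, "gwas_scenario": scenario})

    gdf = pd.DataFrame(gwas_rows)
    truth.genes = truth.genes.merge(gdf, on="gene_id", how="left")

    cat = catalog.copy()
    cat["vid"] = panel.ids
    out_rows = []
    for j in range(m):
        rsid = cat.at[j, "rsid"]
        if rsid is None or (isinstance(rsid, float) and np.isnan(rsid)):
            continue
        f_alt = freqs[j]
        if f_alt <= 0 or f_alt >= 1:
            continue
        se = 1.0 / np.sqrt(2 * f_alt * (1 - f_alt) * cfg.gwas_n)
        beta_alt = mean_beta[j] + float(rng.normal(0, se))
        p = 2 * stats.norm.sf(abs(beta_alt / se))
        if rng.random() < 0.5:  # emit on the ALT allele
            ea, oa, beta, eaf = cat.at[j, "alt"], cat.at[j, "ref"], beta_alt, f_alt
        else:  # emit on the REF allele
            ea, oa, beta, eaf = cat.at[j, "ref"], cat.at[j, "alt"], -beta_alt, 1 - f_alt
        out_rows.append({
            "SNP": rsid, "beta": beta, "se": se, "pval": max(p, 5e-324),
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "n": cfg.gwas_n, "trait": trait,
        })
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> SimData:
    """Run every generator stage in order and bundle the results."""
    panel = gen_haplotypes(cfg)
    catalog, truth = gen_variant_catalog(cfg, panel)
    eqtls, sample_sizes = gen_eqtl_tables(cfg, catalog, panel, truth)
    windows = gen_sweep_windows(cfg, catalog, truth)
    gwas = gen_gwas_summary(cfg, catalog, panel, truth)
    return SimData(config=cfg, panel=panel, catalog=catalog, truth=truth,
                   eqtls=eqtls, sample_sizes=sample_sizes, windows=windows, gwas=gwas)
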