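# Methods

`paleoqtl` implements an analysis pipeline relating *Homo sapiens*-derived,
nearly fixed alleles to cis-eQTL effects in brain tissues. Every stage can be
exercised in "simulate mode" on synthetic inputs with known ground truth;
"real mode" reads the same plain-text dialects from disk. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic generator does and does not emulate.

## Derived-allele classification

A biallelic site enters the derived high-frequency (HF) set when all of the
following hold:

1. **Ancestral state resolvable.** The great-ape alignment call is used when
   present; the macaque reference allele is the fallback for ambiguous loci.
   A call matching neither REF nor ALT marks the site unresolvable; sites
   with no call are excluded.
2. **Derived, nearly fixed.** The derived allele is the major allele
   (a tie at 0.50 fails) and its global frequency is ≥ the threshold
   (default 0.90, compared with ≥ so 0.90 passes). In the stringent mode
   (default) the derived frequency must also be ≥ threshold in each of the
   five metapopulations (AFR, AMR, EAS, EUR, SAS); a global-only mode admits
   sites that dip below the threshold in single populations.
3. **Archaic condition.** Genotypes of the Altai Neanderthal, Vindija
   Neanderthal and Denisovan are first masked by coverage reliability —
   inclusive bounds 5–105× for Altai and 5–75× for the other two; a site
   with no reliable archaic genotype is excluded. The condition is then:
   every reliable archaic is homozygous ancestral, **or** the Denisovan is
   reliable and homozygous ancestral while at least one reliable Neanderthal
   carries a derived allele. The second clause tolerates gene flow from
   modern humans into Neanderthals.

Two readings of "has the ancestral allele" for heterozygous archaics exist;
the strict one (homozygous ancestral required) is the default, the lenient
one is available behind `het_is_ancestral`. A heterozygous Neanderthal
counts as carrying the derived allele in the gene-flow clause
(`het_neanderthal_is_derived`, default on). Coverage failure masks the
individual rather than dropping the site, because the gene-flow clause is
informative on genotype subsets.

Classification is monotone: raising the threshold, or switching from
global-only to stringent, never adds variants. Variants without an rsID are
pruned before mapping onto eQTL tables.

## eQTL intersection and composition tests

The focal set is every FDR-significant eQTL row whose variant is
derived-HF; the background is every other significant row. Tissue and
consequence-category composition are compared by a 2×K chi-square test of
homogeneity. Post-hoc, adjusted (Haberman) residuals

    r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − rowsum_i/N)(1 − colsum_j/N))

are compared with the two-sided normal critical value (1.96 at α = 0.05);
flagged cells are reported as the drivers. When any expected cell is below
5 the asymptotic p is replaced by a Monte-Carlo p (10,000 multinomial
tables from the independence model, +1-corrected). The residual form is a
design choice — several residual conventions exist; the adjusted form is
the one whose null distribution is standard normal.

Caveat: eQTL rows are not independent observations (one variant recurs
across tissues), so composition p-values on row counts are
anti-conservative to the degree the focal set is dominated by few variants.
The calibration property (flags at ≈ α) holds for independent counts, which
is what the test machinery is checked against.

Per-tissue clumped counts are correlated with tissue sample size by
Spearman's rho, with a degree-2 least-squares polynomial fit; tissues whose
residual exceeds one residual standard error of the fit are reported as
outliers. A label-permutation test ("random sampling", default n = 100)
asks whether any tissue holds more tissue-specific clumped eQTLs than
expected: tissue labels are permuted over the clumped assignments
(preserving per-tissue totals), the unique-to-one-tissue count vector is
recomputed, and the observed goodness-of-fit statistic against the
resampling mean is referred to the permutation distribution of the same
statistic. Under exchangeable labels the resulting p is uniform (verified
by KS test in the suite).

## LD and clumping

r² is the squared haplotype correlation computed on a binary haplotype
panel; it is undefined (error) for monomorphic variants. Clumping follows
the Plink convention: sort by ascending nominal p (ties broken by
chromosome, then position), take the best unassigned variant as index,
absorb unassigned variants within `window_kb` (default 250, Plink's
default) with r² ≥ `r2_threshold`. The result is a partition; no member has
smaller p than its index; raising the threshold never reduces the clump
count. The r² threshold is a required, visible parameter with default 0.1.
Variants absent from (or monomorphic in) the panel pass through as
singleton clumps with a warning, mirroring Plink's treatment of unknown
SNPs. Clumping is per tissue by default; pooled clumping is a caller
choice (clump the union once).

## Sweep-overlap permutation test

Windows are BED-convention (0-based half-open) intervals, merged per source
before any counting; a 1-based variant position p lies in [start, end) iff
start ≤ p−1 < end. The test statistic is the number of distinct positions
inside any merged window, computed on the *unclumped* derived-HF eQTL set
(clumping could move index variants outside sweep windows and bleed power).
The empirical p uses the +1 correction, p = (1 + #{perm ≥ obs})/(N + 1),
so it is never zero; N defaults to 1,000.

Two randomization strategies are provided. The default redraws all query
positions uniformly over the genome (chromosome proportional to length).
This null treats the query as exchangeable with uniform points; when the
query set is spatially clustered — as cis-eQTL variants are, sitting in
dense blocks around genes — it underestimates the variance of the overlap
count and becomes anti-conservative (we measure ~3× the nominal type-I
error on clustered synthetic queries). The alternative,
`randomize="windows"`, redraws window locations keeping their lengths,
preserves the query's spatial structure, and is the calibrated choice for
clustered queries; the suite verifies its type-I error sits inside the
exact binomial 95% CI at α = 0.05, and verifies the position-redraw mode is
calibrated on uniform queries, the regime it models.

Between-study comparisons use per-tissue overlap counts normalised by each
study's total merged window length (per megabase): a two-sided Wilcoxon
signed-rank on the paired rates, and a Kruskal–Wallis followed by Dunn's
tie-corrected rank z-tests with Bonferroni adjustment.

## Regulatory directionality

Reported eQTL slopes are ALT-dosage effects; they are re-signed so they
always describe the focal allele (derived, or ancestral in the control).
Exactly-zero slopes are counted separately and excluded. The pooled up/down
count is tested against 50/50 with a one-degree chi-square; per-tissue
binomial z residuals, (up_t − n_t/2)/sqrt(n_t/4), identify skewed tissues
(pooled-then-residual design; a per-tissue-with-correction mode would be a
straightforward variant). The frequency control selects variants whose
*ancestral* allele is major at ≥ the same threshold — a skew that survives
in this mirrored set is an artifact of the frequency cutoff, not of
derived status.

Tissue clustering uses per-tissue mean slopes per gene, pairwise Euclidean
distances with pairwise-complete gene sets (rescaled to the full gene
count), and complete-linkage agglomeration (linkage and metric are
configurable; neither is canonical for this analysis). Dendrograms are
serialisable as Newick.

## Mendelian randomization and colocalization

Instruments are the top eQTL variant per gene × tissue (smallest nominal p,
ties broken by position), kept at p ≤ 5e−4 and required to be present in
the derived-allele catalog — deliberately *not* restricted to HF variants,
since a nearly fixed variant in LD with the true causal one can fake a
causal signal. Harmonization aligns the GWAS record to the instrument's
ALT allele, flipping beta and EAF when the effect allele is swapped;
palindromic variants (A/T, C/G) with effect-allele frequency in
[0.42, 0.58] are dropped (a common convention — strand cannot be resolved
there). The Wald ratio is beta_out/beta_exp with first-order standard
error |se_out/beta_exp| and a two-sided normal p; Bonferroni is applied
over all gene × trait tests of one invocation.

Colocalization uses Wakefield approximate Bayes factors per variant,
log ABF = ½[log(V/(V+W)) + z²W/(V+W)] with V = se² and prior effect
standard deviation 0.15 per quantitative trait, combined into posteriors
over the five standard hypotheses with priors p1 = p2 = 1e−4, p12 = 1e−5.
Sums are computed in log space (logsumexp); posteriors are normalised and
sum to one within 1e−9. Single-variant regions cannot identify the
distinct-causal hypothesis and emit a warning. PP4 is non-decreasing in
p12. Both PP4 alone and PP3+PP4 are available to the caller; which of the
two summarises "shared signal" is a reporting choice.

## The synthetic generator

The generator's role is to produce inputs whose ground truth is known *by
construction*, at the study's default conditions: 15 tissues with sample
sizes in the range of real brain RNA-seq cohorts (114–237), five
metapopulations, a 0.90 frequency threshold, two sweep-window sources,
N = 1,000 permutations, MR threshold 5e−4.

- **Haplotypes** follow Markov template copying: each haplotype copies one
  of 8 founder templates, switching between adjacent variants with
  probability 1 − exp(−d/L) (L = 25 kb). Variants are laid out in dense
  per-gene blocks (20 variants, ~0.2–2.5 kb spacing) across four synthetic
  chromosomes (120 Mb total), giving strong within-gene LD and negligible
  between-gene LD — enough structure for clumping and colocalization, with
  no pretence of demographic realism (no recombination hotspots, no
  population structure, no allele-frequency spectrum from a real
  demography).
- **Catalog.** A configurable fraction (default 0.15) of variants is built
  to satisfy every classification rule (panel columns overwritten so the
  derived allele is genuinely at ≥ 0.92; metapopulation frequencies jittered
  within the passing band; archaic genotypes drawn from one of the two
  qualifying configurations, with occasional coverage-masked individuals).
  Every other variant has at least one rule explicitly broken — derived
  allele minor, Denisovan homozygous derived, all-archaic coverage failure,
  unresolved ancestral state, or (to exercise the stringent filter
  specifically) one metapopulation below threshold with everything else
  passing. Global frequencies equal panel column frequencies exactly.
- **eQTL tables.** Per eQTL gene one causal variant (preferring derived-HF
  variants with probability 0.6) with effect ~ ±U(0.4, 1); marginal slopes
  propagate through LD as b·corr(v, causal) plus noise with standard error
  σ/sqrt(2f(1−f)n_t), so discovery counts rise with tissue sample size for
  free. Significance is Benjamini–Hochberg at 0.05 per tissue — an
  emulation of the real q-value convention, not a re-derivation of it.
  Duplicate tissue pairs (Cerebellum/Cerebellar Hemisphere, Cortex/BA9)
  share activity and effects up to small perturbations. Consequence
  categories come from a fixed eight-label set; per-tissue and per-category
  enrichment multipliers exist for power experiments and default to off
  (homogeneous null).
- **Sweep windows.** Two sources covering 5% and 10% of the genome. With
  enrichment factor ε, a fraction q = min(1, (ε−1)·c·n_HF/W) of windows is
  centred on random derived-HF positions, raising the expected in-window HF
  rate to ≈ ε× background to first order; ε = 1 places every window
  uniformly (the exact null).
- **GWAS summaries.** Per region: H4 reuses the eQTL causal variant with
  effect = ratio × gene effect (default ratio 0.3); H3 picks the
  least-correlated other variant in the block; H2 puts signals only in
  non-eQTL genes; H1/H0 leave the GWAS null. Effect alleles are emitted
  with random REF/ALT orientation so harmonization is genuinely exercised;
  n = 30,000 gives GWAS-scale standard errors.

What passing on this generator does **not** show: behaviour under real
LD patterns, allele-frequency spectra, or pervasive polygenicity; the
composition tests' row-dependence caveat above; robustness to
misannotated ancestral states beyond the explicit unresolvable class.

## Problem sizes and determinism

The default end-to-end simulate run uses 2,000 variants × 400 haplotypes
and completes in well under a minute on one CPU; the test suite's
simulation-heavy checks use 300–5,000 variants and 100–300 haplotypes, and
the permutation-calibration check uses N = 200 permutations per run
(library default N = 1,000). All randomness flows through per-stage
`numpy` generators seeded from (seed, stage index); a rerun with the same
config is byte-identical, verified by SHA-256 manifest comparison.
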