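"""Two-sample Mendelian randomization against a brain-volume-style GWAS,
followed by colocalization of the surviving signals.

Instruments are top eQTL hits per gene x tissue (p <= 5e-4, present in the
derived-allele catalog), harmonized to the GWAS alleles; Wald ratios are
Bonferroni-corrected, and each surviving gene region is tested for a shared
causal variant with approximate-Bayes-factor colocalization (PP4 = shared
signal).
"""

import pandas as pd

from paleoqtl import causal
from paleoqtl.synthio import SimConfig, simulate
from paleoqtl.variant_filter import classify_catalog, drop_unmapped

# H4: the GWAS causal variant IS the eQTL causal variant in every region
data = simulate(SimConfig(n_variants=2000, seed=23, coloc_scenario="H4"))
classified = drop_unmapped(classify_catalog(data.catalog))

derived_ids = set(classified.loc[classified["derived_major"], "rsid"].dropna())
sig = data.eqtls.loc[data.eqtls["qval_pass"]]
instruments = causal.select_instruments(sig, derived_ids, p_threshold=5e-4)
print(f"{len(instruments)} instruments (top eQTL per gene x tissue)")

results = causal.run_mr(instruments, data.gwas)
mr = pd.DataFrame([vars(r) for r in results])
sig_mr = mr.loc[mr["pvalue_adjusted"] < 0.05]
print(f"Wald-ratio tests: {len(mr)}, Bonferroni-significant: {len(sig_mr)}")
print(f"median causal estimate among significant tests: "
      f"{sig_mr['beta'].median():.3f} (simulated ratio {data.config.mr_true_ratio})")

pp4 = []
for _, row in sig_mr.head(20).iterrows():
    eq = data.eqtls.loc[(data.eqtls["gene_id"] == row["gene"])
                        & (data.eqtls["tissue"] == row["tissue"])
                        & data.eqtls["rsid"].notna(),
                        ["rsid", "slope", "slope_se"]].rename(
        columns={"slope": "beta", "slope_se": "se"})
    gw = data.gwas.loc[data.gwas["SNP"].isin(eq["rsid"]),
                       ["SNP", "beta", "se"]].rename(columns={"SNP": "rsid"})
    if len(eq) < 2:
        continue
    pp4.append(causal.coloc_abf(eq, gw)["PP4"])
print(f"mean PP4 over {len(pp4)} MR-surviving regions: "
      f"{sum(pp4) / len(pp4):.2f} (the shared-signal posterior dominates; "
      "under distinct causal variants it would be near zero)")
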