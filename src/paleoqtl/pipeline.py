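"""End-to-end orchestration: simulate (or load) inputs, then run every stage.

One YAML-able config drives the whole run; every stage draws its
randomness from a stream derived from (seed, stage index), so each stage is
independently reproducible and a rerun with the same config is
byte-identical. Each emitted artifact is SHA-256-hashed into a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal, direction, eqtl_join, io, ld, sweep_overlap, synthio
from .variant_filter import classify_catalog, drop_unmapped

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Paths (real mode) or a simulation block, plus all stage thresholds."""

    out_dir: str = "paleoqtl_run"
    seed: int = 0

    # real-mode inputs (all None => simulate)
    catalog_path: str | None = None
    eqtl_path: str | None = None
    panel_path: str | None = None
    sweep_bed_paths: dict = field(default_factory=dict)  # source -> path
    gwas_path: str | None = None
    chrom_lengths: dict | None = None

    # simulate-mode block
    simulate: dict | None = field(default_factory=dict)

    # thresholds
    frequency_threshold: float = 0.90
    stringent_metapop: bool = True
    r2_threshold: float = 0.1
    clump_window_kb: float = 250.0
    n_permutations: int = 1000
    mr_p_threshold: float = 5e-4
    alpha: float = 0.05

    # stage toggles
    stages: tuple = ("classify", "intersect", "enrich", "clump", "sweep",
                     "direction", "mr", "coloc")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    @property
    def simulate_mode(self) -> bool:
        return self.catalog_path is None

    def validate(self) -> None:
        if not 0.5 < self.frequency_threshold <= 1.0:
            raise ValueError("frequency_threshold must be in (0.5, 1]")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.simulate_mode:
            missing = [p for p in [self.catalog_path, self.eqtl_path, self.panel_path,
                                   *self.sweep_bed_paths.values(), self.gwas_path]
                       if p is not None and not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing input file(s): {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute classify -> intersect -> enrich -> clump -> sweep -> direction
    -> MR -> coloc, writing artifacts + manifest under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(config).items()},
                      "stages": {}, "results": {}}

    # ----- inputs
    if config.simulate_mode:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.seed)
        cfg = synthio.SimConfig(**sim_kwargs)
        data = synthio.simulate(cfg)
        catalog, panel, eqtls = data.catalog, data.panel, data.eqtls
        windows = data.windows
        gwas = data.gwas
        sample_sizes = data.sample_sizes
        genome = cfg.chrom_lengths
        io.write_catalog(catalog, out / "catalog.tsv")
        io.write_eqtls(eqtls, out / "eqtls.tsv")
        io.write_haplotypes(panel, out / "haplotypes.tsv")
        io.write_bed(windows, out / "sweeps.bed")
        io.write_gwas(gwas, out / "gwas.tsv")
    else:
        catalog = io.read_catalog(config.catalog_path)
        eqtls = io.read_eqtls(config.eqtl_path)
        panel = io.read_haplotypes(config.panel_path)
        windows = []
        for source, path in config.sweep_bed_paths.items():
            windows.extend(io.read_bed(path, source=source))
        gwas = io.read_gwas(config.gwas_path) if config.gwas_path else None
        sample_sizes = pd.Series(synthio.TISSUE_SAMPLES)
        genome = config.chrom_lengths or {
            c: int(g["pos"].max() + 1_000_000) for c, g in catalog.groupby("chrom")
        }

    def record(stage: str, payload: dict) -> None:
        manifest["results"][stage] = payload
        logger.info("stage %s: %s", stage, payload)

    try:
        # ----- classify
        classified = classify_catalog(
            catalog, threshold=config.frequency_threshold,
            stringent_metapop=config.stringent_metapop,
        )
        mapped = drop_unmapped(classified)
        io.write_catalog(classified, out / "classified.tsv")
        record("classify", {
            "n_variants": int(len(classified)),
            "n_derived_hf": int(classified["is_derived_hf"].sum()),
            "n_with_rsid": int(len(mapped)),
        })

        # ----- intersect
        focal, background = eqtl_join.intersect(mapped, eqtls)
        record("intersect", {
            "n_focal": int(len(focal)), "n_background": int(len(background)),
            "n_egenes": int(focal["gene_id"].nunique()) if len(focal) else 0,
        })

        # ----- enrichment tests
        if len(focal) and "enrich" in config.stages:
            tissue_res = eqtl_join.tissue_composition_test(focal, background,
                                                           alpha=config.alpha)
            cat_res = eqtl_join.category_composition_test(focal, background,
                                                          alpha=config.alpha)
            record("enrich", {
                "tissue_p": tissue_res.pvalue,
                "tissue_flagged": [f"{g}:{t}" for g, t, _ in tissue_res.flagged],
                "category_p": cat_res.pvalue,
                "category_flagged": [f"{g}:{t}" for g, t, _ in cat_res.flagged],
            })

        # ----- clump per tissue
        clumped_frames, clump_sets = [], {}
        for tissue, sub in focal.groupby("tissue"):
            cl = ld.clump(sub.rename(columns={"pval_nominal": "pval"}), panel,
                          r2_threshold=config.r2_threshold,
                          window_kb=config.clump_window_kb, tissue=tissue)
            clump_sets[tissue] = cl
            clumped_frames.append(ld.clumps_to_frame(cl))
        clumped = (pd.concat(clumped_frames, ignore_index=True)
                   if clumped_frames else pd.DataFrame(
                       columns=["rsid", "chrom", "pos", "pval", "n_members", "tissue"]))
        clumped.to_csv(out / "clumped.tsv", sep="\t", index=False)
        specific = ld.tissue_specific(clump_sets) if clump_sets else pd.Series(dtype=int)
        record("clump", {
            "n_clumped": int(len(clumped)),
            "n_unique_index_variants": int(clumped["rsid"].nunique()) if len(clumped) else 0,
            "n_tissue_specific": int(specific.sum()) if len(specific) else 0,
        })

        if len(clumped):
            counts = clumped.groupby("tissue")["rsid"].nunique()
            corr = eqtl_join.sample_size_correlation(counts, sample_sizes)
            samp = eqtl_join.region_specific_sampling_test(
                clumped[["rsid", "tissue"]], n_resamples=100, seed=config.seed)
            record("tissue_stats", {
                "spearman_rho": corr.rho, "spearman_p": corr.pvalue,
                "fit_outliers": corr.outliers,
                "region_sampling_p": samp.pvalue,
            })

        # ----- sweep permutation tests (unclumped derived-HF eQTL positions)
        positions = focal[["chrom", "pos"]].drop_duplicates()
        sweep_payload = {}
        for i, source in enumerate(sorted({w.source for w in windows})):
            ws = [w for w in windows if w.source == source]
            res = sweep_overlap.permutation_test(
                positions, ws, genome, n_permutations=config.n_permutations,
                seed=np.random.default_rng(np.random.SeedSequence([config.seed, 100 + i])),
            )
            sweep_payload[source] = res.to_dict()
        if windows and len(positions):
            rates = sweep_overlap.per_region_counts(
                focal, {s: [w for w in windows if w.source == s]
                        for s in sorted({w.source for w in windows})})
            rates.to_csv(out / "sweep_region_counts.tsv", sep="\t", index=False)
            try:
                sweep_payload["between_sources"] = {
                    k: v for k, v in sweep_overlap.compare_sources(rates).items()
                    if not isinstance(v, pd.DataFrame)
                }
            except ValueError as err:
                sweep_payload["between_sources"] = {"error": str(err)}
        record("sweep", sweep_payload)

        # ----- direction
        oriented = direction.orient_slopes(focal, mapped, focal="derived")
        unclumped_table = direction.build_direction_table(focal, oriented, "unclumped-derived")
        dir_payload = {}
        if unclumped_table.total_up + unclumped_table.total_down:
            res_u = direction.direction_test(unclumped_table, alpha=config.alpha)
            dir_payload["unclumped"] = {"statistic": res_u.statistic, "p": res_u.pvalue,
                                        "n_up": res_u.n_up, "n_down": res_u.n_down,
                                        "flagged": res_u.flagged_tissues}
        if len(clumped):
            index_pairs = set(zip(clumped["rsid"], clumped["tissue"]))
            keep = pd.Series(list(zip(focal["rsid"], focal["tissue"])),
                             index=focal.index).isin(index_pairs)
            cl_focal = focal.loc[keep]
            cl_table = direction.build_direction_table(
                cl_focal, oriented[keep], "clumped-derived")
            if cl_table.total_up + cl_table.total_down:
                res_c = direction.direction_test(cl_table, alpha=config.alpha)
                dir_payload["clumped"] = {"statistic": res_c.statistic, "p": res_c.pvalue,
                                          "n_up": res_c.n_up, "n_down": res_c.n_down}
        control_table = direction.build_control_set(mapped, eqtls,
                                                    threshold=config.frequency_threshold)
        if control_table.total_up + control_table.total_down:
            res_ctrl = direction.direction_test(control_table, alpha=config.alpha)
            dir_payload["control"] = {"statistic": res_ctrl.statistic, "p": res_ctrl.pvalue,
                                      "n_up": res_ctrl.n_up, "n_down": res_ctrl.n_down}
        if len(focal):
            linkage, tissues, _ = direction.tissue_clustering(focal, oriented)
            (out / "tissue_dendrogram.nwk").write_text(
                direction.linkage_to_newick(linkage, tissues))
        record("direction", dir_payload)

        # ----- MR + coloc
        if gwas is not None and "mr" in config.stages:
            derived_ids = set(mapped.loc[mapped["derived_major"], "rsid"].dropna())
            instruments = causal.select_instruments(
                eqtls.loc[eqtls["qval_pass"]], derived_ids,
                p_threshold=config.mr_p_threshold)
            mr_results = causal.run_mr(instruments, gwas)
            mr_df = pd.DataFrame([vars(r) for r in mr_results])
            mr_df.to_csv(out / "mr_results.tsv", sep="\t", index=False)
            n_sig = int((mr_df["pvalue_adjusted"] < config.alpha).sum()) if len(mr_df) else 0
            record("mr", {"n_instruments": int(len(instruments)),
                          "n_tests": int(len(mr_df)), "n_significant": n_sig})

            coloc_payload = []
            if len(mr_df):
                # allele orientation is irrelevant to the ABFs (only z² enters)
                gw = gwas
                survivors = mr_df.loc[mr_df["pvalue_adjusted"] < config.alpha]
                for _, row in survivors.iterrows():
                    region_eq = eqtls.loc[(eqtls["gene_id"] == row["gene"])
                                          & (eqtls["tissue"] == row["tissue"])
                                          & eqtls["rsid"].notna(),
                                          ["rsid", "slope", "slope_se"]].rename(
                        columns={"slope": "beta", "slope_se": "se"})
                    region_gw = gw.loc[gw["SNP"].isin(region_eq["rsid"]),
                                       ["SNP", "beta", "se"]].rename(columns={"SNP": "rsid"})
                    if len(region_eq) == 0 or len(region_gw) == 0:
                        continue
                    res = causal.coloc_abf(region_eq, region_gw)
                    coloc_payload.append({"gene": row["gene"], "tissue": row["tissue"],
                                          **res.pp})
                pd.DataFrame(coloc_payload).to_csv(out / "coloc_results.tsv",
                                                   sep="\t", index=False)
            record("coloc", {
                "n_regions": len(coloc_payload),
                "mean_pp4": float(np.mean([c["PP4"] for c in coloc_payload]))
                if coloc_payload else None,
            })
    except Exception as err:  # noqa: BLE001 - name the failing stage, keep partials
        done = list(manifest["results"])
        stage = "unknown"
        raise RuntimeError(
            f"pipeline aborted after stages {done}: {type(err).__name__}: {err}"
        ) from err

    # ----- manifest
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")) + sorted(out.glob("*.nwk")):
        manifest["stages"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
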