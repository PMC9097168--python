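"""Classifier unit tests: coverage bounds, ancestral assignment, the archaic
condition against an exhaustive enumeration oracle, threshold behaviour and
monotonicity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paleoqtl.synthio import SimConfig, gen_haplotypes, gen_variant_catalog
from paleoqtl.variant_filter import (
    archaic_condition,
    assign_ancestral,
    classify_catalog,
    classify_record,
    coverage_pass,
    drop_unmapped,
)

from conftest import make_catalog_row


@pytest.mark.parametrize(
    "dp,expect",
    [
        ((4, 40, 40), {"altai": False, "vindija": True, "denisova": True}),
        ((5, 40, 40), {"altai": True, "vindija": True, "denisova": True}),
        ((105, 40, 40), {"altai": True, "vindija": True, "denisova": True}),
        ((106, 40, 40), {"altai": False, "vindija": True, "denisova": True}),
        ((50, 76, 40), {"altai": True, "vindija": False, "denisova": True}),
        ((50, 75, 75), {"altai": True, "vindija": True, "denisova": True}),
        ((50, 40, 76), {"altai": True, "vindija": True, "denisova": False}),
        ((50, 40, None), {"altai": True, "vindija": True, "denisova": False}),
    ],
)
def test_coverage_bounds_inclusive(dp, expect):
    out = coverage_pass(*dp)
    for k, v in expect.items():
        assert out[k] == v
    assert out["any"] == any(expect.values())


def test_negative_coverage_rejected():
    with pytest.raises(ValueError, match="negative"):
        coverage_pass(-1, 40, 40)


@pytest.mark.parametrize(
    "ape,mac,expected_allele,expected_source",
    [
        ("A", None, "A", "from_apes"),
        ("A", "G", "A", "from_apes"),  # ape call takes precedence
        (None, "G", "G", "from_macaque"),
        (None, None, None, "unknown"),
        ("T", None, None, "unresolvable"),  # matches neither ref nor alt
    ],
)
def test_assign_ancestral(ape, mac, expected_allele, expected_source):
    allele, source = assign_ancestral(ape, mac, ref="A", alt="G")
    assert allele == expected_allele
    assert source == expected_source


def _oracle(genotypes, reliable, ancestral_index):
    """Independent enumeration of the archaic-ancestrality condition.

    Informative = reliable and non-missing. Clause 1: every informative
    individual homozygous for the ancestral allele. Clause 2: Denisovan
    informative and homozygous ancestral, and some informative Neanderthal
    carries at least one derived allele.
    """
    der = 1 - ancestral_index
    anc_hom = {(ancestral_index, ancestral_index)}

    def alleles(name):
        gt = genotypes[name]
        if gt == "./." or not reliable[name]:
            return None
        a, b = gt.split("/")
        return (int(a), int(b))

    info = {n: alleles(n) for n in ("altai", "vindija", "denisova")}
    if all(v is None for v in info.values()):
        return None  # undecidable
    clause1 = all(v in anc_hom for v in info.values() if v is not None)
    clause2 = info["denisova"] in anc_hom and any(
        info[n] is not None and der in info[n] for n in ("altai", "vindija")
    )
    return clause1 or clause2


def test_archaic_condition_matches_enumeration_oracle():
    """All 4^3 genotype combinations x 2^3 reliability masks x both
    ancestral orientations agree with the independent oracle."""
    gts = ["0/0", "0/1", "1/1", "./."]
    checked = 0
    for combo in itertools.product(gts, repeat=3):
        genotypes = dict(zip(("altai", "vindija", "denisova"), combo))
        for mask in itertools.product([True, False], repeat=3):
            reliable = dict(zip(("altai", "vindija", "denisova"), mask))
            for anc_idx in (0, 1):
                expected = _oracle(genotypes, reliable, anc_idx)
                if expected is None:
                    with pytest.raises(ValueError):
                        archaic_condition(genotypes, reliable, anc_idx)
                else:
                    got = archaic_condition(genotypes, reliable, anc_idx)
                    assert got == expected, (genotypes, reliable, anc_idx)
                checked += 1
    assert checked == 4 ** 3 * 2 ** 3 * 2


def test_gene_flow_clause():
    """Denisovan ancestral + one Neanderthal derived qualifies even though
    the all-ancestral clause fails; a derived Denisovan never qualifies."""
    rel = {"altai": True, "vindija": True, "denisova": True}
    assert archaic_condition(
        {"altai": "./.", "vindija": "0/1", "denisova": "0/0"},
        {"altai": False, "vindija": True, "denisova": True}, 0)
    assert not archaic_condition(
        {"altai": "0/0", "vindija": "0/0", "denisova": "1/1"}, rel, 0)


def test_het_reading_flags():
    """A heterozygous archaic fails the strict all-ancestral clause but can
    pass under the lenient reading."""
    rel = {"altai": True, "vindija": True, "denisova": True}
    gts = {"altai": "0/1", "vindija": "0/0", "denisova": "1/1"}
    # denisova derived: clause 2 dead; clause 1 depends on het reading
    assert not archaic_condition(gts, rel, 0, het_is_ancestral=False)
    gts2 = {"altai": "0/1", "vindija": "0/0", "denisova": "0/1"}
    assert not archaic_condition(gts2, rel, 0, het_is_ancestral=False)
    assert archaic_condition(gts2, rel, 0, het_is_ancestral=True)


class TestClassify:
    def test_full_pass(self):
        flags = classify_record(make_catalog_row())
        assert flags.is_derived_hf
        assert flags.derived_major and flags.hf_global and flags.hf_all_metapops

    def test_stringent_vs_global_only(self):
        row = make_catalog_row(af_global=0.92, af_EAS=0.85)
        assert not classify_record(row, stringent_metapop=True).is_derived_hf
        assert classify_record(row, stringent_metapop=False).is_derived_hf

    def test_fixed_only_at_threshold_one(self):
        row = make_catalog_row(af_global=0.98)
        assert not classify_record(row, threshold=1.0).is_derived_hf
        fixed = make_catalog_row(
            af_global=1.0, **{f"af_{m}": 1.0 for m in ("AFR", "AMR", "EAS", "EUR", "SAS")}
        )
        assert classify_record(fixed, threshold=1.0).is_derived_hf

    def test_major_allele_tie_fails(self):
        row = make_catalog_row(
            af_global=0.5, **{f"af_{m}": 0.5 for m in ("AFR", "AMR", "EAS", "EUR", "SAS")}
        )
        assert not classify_record(row).derived_major

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            classify_record(make_catalog_row(), threshold=0.4)

    def test_derived_orientation_respected(self):
        """When ALT is ancestral, the derived allele is REF and frequencies
        must be complemented before thresholding."""
        row = make_catalog_row(
            ancestral_allele="G", af_global=0.05,
            **{f"af_{m}": 0.05 for m in ("AFR", "AMR", "EAS", "EUR", "SAS")},
            gt_altai="1/1", gt_vindija="1/1", gt_denisova="1/1",
        )
        assert classify_record(row).is_derived_hf

    def test_unresolved_ancestral_excluded(self):
        row = make_catalog_row(ancestral_allele=".", ancestral_call="unknown")
        flags = classify_record(row)
        assert not flags.is_derived_hf
        assert flags.exclusion_reason == "ancestral_unresolved"

    def test_no_reliable_archaic_excluded(self):
        row = make_catalog_row(dp_altai=2, dp_vindija=0, dp_denisova=200)
        flags = classify_record(row)
        assert flags.exclusion_reason == "no_reliable_archaic"


def test_threshold_and_stringency_monotonicity():
    """Raising the threshold never adds variants; the stringent set is a
    subset of the global-only set. Checked on generated catalogs."""
    cfg = SimConfig(n_variants=400, n_haplotypes=150, seed=7)
    panel = gen_haplotypes(cfg)
    catalog, _ = gen_variant_catalog(cfg, panel)
    sets = {}
    for thr in (0.90, 0.93, 0.97):
        cl = classify_catalog(catalog, threshold=thr)
        sets[thr] = set(cl.index[cl["is_derived_hf"]])
    assert sets[0.97] <= sets[0.93] <= sets[0.90]
    loose = classify_catalog(catalog, stringent_metapop=False)
    assert sets[0.90] <= set(loose.index[loose["is_derived_hf"]])


def test_ground_truth_round_trip():
    """Generated labels are recovered exactly by the classifier."""
    for seed in (1, 2, 3):
        cfg = SimConfig(n_variants=500, n_haplotypes=200, seed=seed)
        panel = gen_haplotypes(cfg)
        catalog, truth = gen_variant_catalog(cfg, panel)
        cl = classify_catalog(catalog)
        assert (cl["is_derived_hf"].to_numpy()
                == truth.variants["is_derived_hf"].to_numpy()).all()


def test_drop_unmapped_counts():
    df = pd.DataFrame({
        "rsid": ["rs1", None, "rs3", None, None, "rs6", "rs7", "rs8", "rs9", "rs10"],
    })
    df["has_rsid"] = df["rsid"].notna()
    out = drop_unmapped(df)
    assert len(out) == 7
    all_mapped = drop_unmapped(out)
    assert len(all_mapped) == 7
    none = df.loc[~df["has_rsid"]]
    assert len(drop_unmapped(none)) == 0
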