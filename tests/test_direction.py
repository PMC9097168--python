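"""Direction test closed forms, sign symmetry, the ancestral-major control
set, and tissue clustering geometry."""

import numpy as np
import pandas as pd
import pytest

from paleoqtl.direction import (
    DirectionTable,
    build_control_set,
    build_direction_table,
    direction_test,
    linkage_to_newick,
    orient_slopes,
    tissue_clustering,
)


def _table(up, down, tissue="T0"):
    return DirectionTable(
        counts=pd.DataFrame({"up": [up], "down": [down]}, index=[tissue]),
        subset="test",
    )


class TestDirectionTest:
    def test_exact_null(self):
        res = direction_test(_table(50, 50))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_75_25(self):
        # (75-50)^2/50 + (25-50)^2/50 = 25
        res = direction_test(_table(75, 25))
        assert res.statistic == pytest.approx(25.0)
        assert res.pvalue < 1e-6

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            direction_test(_table(0, 0))

    def test_skewed_tissue_flagged(self):
        counts = pd.DataFrame({"up": [50, 90], "down": [50, 10]}, index=["A", "B"])
        res = direction_test(DirectionTable(counts=counts, subset="x"))
        assert res.flagged_tissues == ["B"]

    def test_rejection_rate_near_alpha_under_symmetric_generator(self):
        rng = np.random.default_rng(17)
        rejected = 0
        n_rep = 500
        for _ in range(n_rep):
            up = rng.binomial(400, 0.5)
            res = direction_test(_table(up, 400 - up))
            rejected += res.pvalue < 0.05
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], n_rep, 0.05)
        assert lo <= rejected <= hi


class TestOrientation:
    def _classified(self):
        return pd.DataFrame({
            "rsid": ["rs1", "rs2", "rs3"],
            "ref": ["A", "A", "A"], "alt": ["G", "G", "G"],
            "ancestral_allele": ["A", "G", None],
        })

    def _eqtls(self, slopes):
        return pd.DataFrame({
            "rsid": ["rs1", "rs2", "rs3"], "tissue": ["T"] * 3, "slope": slopes,
        })

    def test_derived_orientation(self):
        # rs1: ancestral=REF so derived=ALT, slope unchanged;
        # rs2: ancestral=ALT so derived=REF, slope negated; rs3 unresolved
        out = orient_slopes(self._eqtls([0.5, 0.5, 0.5]), self._classified())
        assert out.tolist()[:2] == [0.5, -0.5]
        assert np.isnan(out.iloc[2])

    def test_ancestral_orientation_is_mirror(self):
        der = orient_slopes(self._eqtls([0.5, -0.2, 0.1]), self._classified(),
                            focal="derived")
        anc = orient_slopes(self._eqtls([0.5, -0.2, 0.1]), self._classified(),
                            focal="ancestral")
        np.testing.assert_allclose(der[:2], -anc[:2])

    def test_sign_symmetry_of_statistic(self):
        """Negating every slope swaps up/down and preserves the statistic."""
        rng = np.random.default_rng(4)
        eq = pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(200)],
            "tissue": rng.choice(["A", "B"], 200),
            "slope": rng.normal(0.2, 1, 200),
        })
        cl = pd.DataFrame({"rsid": eq["rsid"], "ref": "A", "alt": "G",
                           "ancestral_allele": "A"})
        t1 = build_direction_table(eq, orient_slopes(eq, cl), "a")
        eq_neg = eq.assign(slope=-eq["slope"])
        t2 = build_direction_table(eq_neg, orient_slopes(eq_neg, cl), "b")
        assert t1.total_up == t2.total_down and t1.total_down == t2.total_up
        assert direction_test(t1).statistic == pytest.approx(
            direction_test(t2).statistic)

    def test_zero_slopes_excluded(self):
        eq = pd.DataFrame({"rsid": ["rs1", "rs2"], "tissue": ["A", "A"],
                           "slope": [0.0, 1.0]})
        cl = pd.DataFrame({"rsid": eq["rsid"], "ref": "A", "alt": "G",
                           "ancestral_allele": "A"})
        table = build_direction_table(eq, orient_slopes(eq, cl), "x")
        assert table.n_zero_slopes == 1
        assert table.total_up == 1 and table.total_down == 0


class TestControlSet:
    def _classified(self, af, anc_is_ref):
        n = len(af)
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(n)],
            "ref": ["A"] * n, "alt": ["G"] * n,
            "ancestral_allele": ["A" if x else "G" for x in anc_is_ref],
            "af_global": af,
            "ancestral_resolved": [True] * n,
        })

    def _eqtls(self, n):
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(n)], "tissue": ["T"] * n,
            "slope": np.linspace(-1, 1, n), "qval_pass": [True] * n,
        })

    def test_every_major_derived_gives_empty_control(self):
        # ancestral = REF with ALT (derived) frequency 0.95 everywhere:
        # the ancestral allele is never major
        cl = self._classified([0.95] * 5, [True] * 5)
        with pytest.warns(UserWarning, match="empty"):
            table = build_control_set(cl, self._eqtls(5))
        assert table.total_up + table.total_down == 0

    def test_ancestral_major_selected(self):
        # rs0: ancestral REF at 0.95 (af_global ALT=0.05) -> control member
        cl = self._classified([0.05, 0.95, 0.5], [True, True, True])
        table = build_control_set(cl, self._eqtls(3))
        assert table.total_up + table.total_down == 1

    def test_mirror_symmetry(self):
        """A catalog mirrored ref<->alt yields the same control counts with
        up/down swapped."""
        af = [0.05, 0.03, 0.08]
        cl = self._classified(af, [True, True, True])
        eq = self._eqtls(3)
        t1 = build_control_set(cl, eq)
        mirrored = cl.assign(ancestral_allele="G", af_global=[1 - a for a in af])
        t2 = build_control_set(mirrored, eq)
        assert t1.total_up == t2.total_down
        assert t1.total_down == t2.total_up


class TestClustering:
    def _eqtls(self, profiles: dict):
        rows = []
        for tissue, effs in profiles.items():
            for g, e in enumerate(effs):
                rows.append({"tissue": tissue, "gene_id": f"G{g}", "slope": e})
        return pd.DataFrame(rows)

    def test_identical_profiles_merge_at_zero(self):
        eq = self._eqtls({"A": [1, 2, 3], "B": [1, 2, 3], "C": [9, 9, 9]})
        linkage, labels, dist = tissue_clustering(eq)
        assert linkage[0, 2] == pytest.approx(0.0)  # first merge at height 0
        i, j = labels.index("A"), labels.index("B")
        assert dist[i, j] == pytest.approx(0.0)

    def test_opposite_profile_joins_last(self):
        eq = self._eqtls({"A": [1, 2, 3], "B": [1.1, 2.1, 2.9], "C": [-1, -2, -3]})
        linkage, labels, _ = tissue_clustering(eq)
        # the last merge attaches the outlier: its height dominates
        assert linkage[-1, 2] > linkage[0, 2]
        first = {int(linkage[0, 0]), int(linkage[0, 1])}
        assert first == {labels.index("A"), labels.index("B")}

    def test_order_invariance(self):
        eq = self._eqtls({"A": [1, 0, 2], "B": [0, 1, 1], "C": [5, 5, 0]})
        l1, lab1, _ = tissue_clustering(eq)
        eq_rev = eq.iloc[::-1].reset_index(drop=True)
        l2, lab2, _ = tissue_clustering(eq_rev)
        assert lab1 == lab2  # pivot sorts tissues
        np.testing.assert_allclose(l1, l2)

    def test_metric_axioms(self):
        rng = np.random.default_rng(2)
        eq = self._eqtls({t: rng.normal(0, 1, 6) for t in "ABCDE"})
        _, _, dist = tissue_clustering(eq)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0)
        k = dist.shape[0]
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    assert dist[i, j] <= dist[i, m] + dist[m, j] + 1e-9

    def test_single_tissue_error(self):
        with pytest.raises(ValueError):
            tissue_clustering(self._eqtls({"A": [1, 2]}))

    def test_newick_serialisation(self):
        eq = self._eqtls({"A": [1, 2], "B": [1, 3], "C": [5, 5]})
        linkage, labels, _ = tissue_clustering(eq)
        nwk = linkage_to_newick(linkage, labels)
        assert nwk.endswith(";")
        for t in labels:
            assert t in nwk
        assert nwk.count("(") == nwk.count(")") == 2
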