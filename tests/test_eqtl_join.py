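"""Contingency machinery against closed-form hand computations, margin
conservation, residual symmetry, enrichment detection, the sample-size
correlation and the label-permutation sampling test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleoqtl.eqtl_join import (
    adjusted_residuals,
    category_composition_test,
    composition_test,
    intersect,
    region_specific_sampling_test,
    sample_size_correlation,
    tissue_composition_test,
)


def hand_chi2(obs):
    """Closed-form chi-square of independence, written out longhand."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / n
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def hand_adjusted_residual(obs, i, j):
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    e = obs[i].sum() * obs[:, j].sum() / n
    return (obs[i, j] - e) / np.sqrt(
        e * (1 - obs[i].sum() / n) * (1 - obs[:, j].sum() / n)
    )


class TestIntersect:
    def _eqtls(self, rsids, sig=True):
        return pd.DataFrame({
            "rsid": rsids, "tissue": ["Cerebellum"] * len(rsids),
            "qval_pass": [sig] * len(rsids),
        })

    def _classified(self, rsids, hf):
        return pd.DataFrame({"rsid": rsids, "is_derived_hf": hf})

    def test_empty_classified(self):
        with pytest.warns(UserWarning, match="empty intersection"):
            focal, background = intersect(
                self._classified(["rs1"], [False]), self._eqtls(["rs1", "rs2"]))
        assert len(focal) == 0 and len(background) == 2

    def test_all_derived(self):
        focal, background = intersect(
            self._classified(["rs1", "rs2"], [True, True]),
            self._eqtls(["rs1", "rs2"]))
        assert len(focal) == 2 and len(background) == 0

    def test_counts_40_60(self):
        rsids = [f"rs{i}" for i in range(100)]
        focal, background = intersect(
            self._classified(rsids, [i < 40 for i in range(100)]),
            self._eqtls(rsids))
        assert len(focal) == 40 and len(background) == 60

    def test_insignificant_rows_excluded(self):
        eq = pd.concat([self._eqtls(["rs1"]), self._eqtls(["rs2"], sig=False)])
        focal, background = intersect(
            self._classified(["rs1", "rs2"], [True, True]), eq)
        assert list(focal["rsid"]) == ["rs1"]


class TestComposition:
    def test_chi2_matches_hand_computation_2x2(self):
        obs = [[10, 90], [50, 850]]
        res = composition_test(pd.Series(obs[0], index=["a", "b"]),
                               pd.Series(obs[1], index=["a", "b"]))
        assert res.statistic == pytest.approx(hand_chi2(obs))
        for i, grp in enumerate(("focal", "background")):
            for j, cat in enumerate(("a", "b")):
                assert res.residuals.loc[grp, cat] == pytest.approx(
                    hand_adjusted_residual(obs, i, j))

    def test_margins_conserved_exactly(self):
        rng = np.random.default_rng(0)
        f = pd.Series(rng.integers(20, 200, 15), index=range(15))
        b = pd.Series(rng.integers(200, 900, 15), index=range(15))
        res = composition_test(f, b)
        np.testing.assert_allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))

    def test_residual_swap_symmetry(self):
        """Swapping focal and background flips residual signs only."""
        f = pd.Series([30, 50, 90], index=list("abc"))
        b = pd.Series([300, 200, 400], index=list("abc"))
        r1 = composition_test(f, b).residuals
        r2 = composition_test(b, f).residuals
        # focal residuals of one ordering equal background residuals of the other
        np.testing.assert_allclose(r1.loc["focal"].to_numpy(), r2.loc["background"].to_numpy())
        np.testing.assert_allclose(r1.loc["focal"].to_numpy(), -r2.loc["focal"].to_numpy())

    def test_homogeneous_large_counts_no_flags(self):
        f = pd.Series([1000] * 10, index=range(10))
        b = pd.Series([5000] * 10, index=range(10))
        res = composition_test(f, b)
        assert res.pvalue > 0.99
        assert res.flagged == []

    def test_enriched_tissues_flagged(self):
        """3x enrichment injected into two tissues is detected with positive
        focal residuals in nearly every replicate."""
        rng = np.random.default_rng(12)
        base = np.ones(15) / 15
        boosted = base.copy()
        boosted[[2, 7]] *= 3
        boosted /= boosted.sum()
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            f = pd.Series(rng.multinomial(600, boosted), index=range(15))
            b = pd.Series(rng.multinomial(6000, base), index=range(15))
            res = composition_test(f, b)
            flagged_pos = {c for g, c, r in res.flagged if g == "focal" and r > 0}
            if {2, 7} <= flagged_pos:
                hits += 1
        assert hits >= 95

    def test_small_counts_use_monte_carlo(self):
        f = pd.Series([2, 1, 0], index=list("abc"))
        b = pd.Series([30, 20, 10], index=list("abc"))
        with pytest.warns(UserWarning, match="Monte-Carlo"):
            res = composition_test(f, b, monte_carlo_resamples=500)
        assert res.monte_carlo
        assert 0 < res.pvalue <= 1

    def test_single_category_degenerate(self):
        with pytest.raises(ValueError):
            composition_test(pd.Series([10], index=["a"]), pd.Series([20], index=["a"]))

    def test_tissue_and_category_wrappers(self):
        f = pd.DataFrame({"tissue": ["A"] * 30 + ["B"] * 20,
                          "consequence": ["intron"] * 25 + ["5'UTR"] * 25})
        b = pd.DataFrame({"tissue": ["A"] * 300 + ["B"] * 200,
                          "consequence": ["intron"] * 250 + ["5'UTR"] * 250})
        assert tissue_composition_test(f, b).pvalue > 0.5
        assert category_composition_test(f, b).pvalue > 0.5


class TestSampleSizeCorrelation:
    def test_perfect_monotone(self):
        counts = pd.Series([10, 20, 30, 40, 55], index=list("abcde"))
        samples = pd.Series([100, 120, 150, 180, 200], index=list("abcde"))
        res = sample_size_correlation(counts, samples)
        assert res.rho == pytest.approx(1.0)

    def test_independent_counts_rarely_significant(self):
        rng = np.random.default_rng(3)
        samples = pd.Series(np.linspace(100, 250, 15), index=range(15))
        n_sig = 0
        for _ in range(100):
            counts = pd.Series(rng.poisson(50, 15), index=range(15))
            res = sample_size_correlation(counts, samples)
            n_sig += res.pvalue < 0.05
        assert n_sig <= 10

    def test_constructed_outlier_reported(self):
        samples = pd.Series(np.linspace(100, 240, 8), index=list("abcdefgh"))
        counts = pd.Series(np.linspace(10, 45, 8), index=list("abcdefgh"))
        counts["d"] *= 5  # way off the smooth trend
        res = sample_size_correlation(counts, samples)
        assert "d" in res.outliers

    def test_constant_counts_error(self):
        with pytest.raises(ValueError, match="constant"):
            sample_size_correlation(pd.Series([5] * 6, index=range(6)),
                                    pd.Series(range(6), index=range(6)))


class TestRegionSpecificSampling:
    def _clumped(self, rng, n=120, tissues=6):
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in rng.integers(0, 40, n)],
            "tissue": [f"T{j}" for j in rng.integers(0, tissues, n)],
        })

    def test_exchangeable_labels_uniform_p(self):
        """Under label exchangeability the permutation p is ~U(0,1)."""
        rng = np.random.default_rng(7)
        pvals = [
            region_specific_sampling_test(self._clumped(rng), n_resamples=60,
                                          seed=int(rng.integers(1 << 30))).pvalue
            for _ in range(200)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_forced_concentration_small_p(self):
        """All tissue-specific eQTLs pushed into one tissue gives small p."""
        rows = []
        for j in range(5):
            for i in range(12):
                rows.append({"rsid": f"shared{i}", "tissue": f"T{j}"})
        for i in range(25):
            rows.append({"rsid": f"only{i}", "tissue": "T0"})
        res = region_specific_sampling_test(pd.DataFrame(rows), n_resamples=200, seed=1)
        assert res.pvalue < 0.05

    def test_no_unique_eqtls_skipped(self):
        df = pd.DataFrame({"rsid": ["rs1", "rs1"], "tissue": ["A", "B"]})
        with pytest.warns(UserWarning, match="skipped"):
            res = region_specific_sampling_test(df, n_resamples=10)
        assert np.isnan(res.pvalue)

    def test_zero_resamples_error(self):
        with pytest.raises(ValueError):
            region_specific_sampling_test(
                pd.DataFrame({"rsid": ["rs1"], "tissue": ["A"]}), n_resamples=0)
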