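"""Intersect classified variants with eQTL tables; composition tests.

The focal set is every significant eQTL row whose variant is in the
derived-HF classified set; the background is every other significant eQTL
row. Composition across tissues (or consequence categories) is compared by
a 2 x K chi-square test of homogeneity with per-cell adjusted (Haberman)
residuals,

    r_ij = (O_ij − E_ij) / sqrt( E_ij (1 − rowsum_i/N) (1 − colsum_j/N) ),

flagging cells with |r| above the two-sided normal critical value as the
drivers of a significant test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult", "intersect", "composition_test",
    "tissue_composition_test", "category_composition_test",
    "adjusted_residuals", "sample_size_correlation",
    "region_specific_sampling_test",
]


def intersect(
    classified: pd.DataFrame, eqtls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split significant eQTL rows into derived-HF (focal) and background.

    ``classified`` is the classifier output (needs ``rsid`` and
    ``is_derived_hf``); ``eqtls`` needs ``rsid`` and the ``qval_pass``
    significance flag. Rows without an rsid cannot be mapped and are
    excluded from both sets.
    """
    hf_ids = set(classified.loc[classified["is_derived_hf"], "rsid"].dropna())
    sig = eqtls.loc[eqtls["qval_pass"] & eqtls["rsid"].notna()]
    focal = sig.loc[sig["rsid"].isin(hf_ids)].reset_index(drop=True)
    background = sig.loc[~sig["rsid"].isin(hf_ids)].reset_index(drop=True)
    if len(focal) == 0:
        warnings.warn("empty intersection: no derived-HF variant is a significant eQTL",
                      stacklevel=2)
    return focal, background


def adjusted_residuals(observed: np.ndarray) -> np.ndarray:
    """Haberman adjusted residuals for an r x c contingency table."""
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    rows = observed.sum(axis=1, keepdims=True)
    cols = observed.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1 - rows / n) * (1 - cols / n))
        r = (observed - expected) / denom
    return r


@dataclass
class ContingencyResult:
    """Chi-square homogeneity test with post-hoc adjusted residuals."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    statistic: float
    dof: int
    pvalue: float
    residuals: pd.DataFrame
    flagged: list
    alpha: float
    monte_carlo: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "dof": self.dof, "pvalue": self.pvalue,
            "alpha": self.alpha, "flagged": list(self.flagged),
            "monte_carlo": self.monte_carlo,
        }


def composition_test(
    focal_counts: pd.Series,
    background_counts: pd.Series,
    alpha: float = 0.05,
    monte_carlo_resamples: int = 10_000,
    seed: int = 0,
) -> ContingencyResult:
    """2 x K homogeneity chi-square with adjusted-residual post-hoc flags.

    When any expected cell falls below 5 the asymptotic p-value is
    unreliable; a Monte-Carlo p is then computed by resampling tables from
    the independence model with fixed total (``monte_carlo_resamples``
    draws, +1-corrected empirical p) and reported instead.
    """
    labels = sorted(set(focal_counts.index) | set(background_counts.index))
    if len(labels) < 2:
        raise ValueError("composition test needs at least two categories")
    obs = np.zeros((2, len(labels)))
    obs[0] = [focal_counts.get(k, 0) for k in labels]
    obs[1] = [background_counts.get(k, 0) for k in labels]
    keep = obs.sum(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two categories with nonzero totals")
    obs = obs[:, keep]
    labels = [k for k, kp in zip(labels, keep) if kp]
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("one of the two groups is empty")

    statistic, pvalue, dof, expected = stats.chi2_contingency(obs, correction=False)
    mc = False
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; using Monte-Carlo p-value", stacklevel=2)
        mc = True
        pvalue = _monte_carlo_p(obs, statistic, monte_carlo_resamples, seed)

    resid = adjusted_residuals(obs)
    crit = stats.norm.ppf(1 - alpha / 2)
    flagged = [(("focal", "background")[i], labels[j], float(resid[i, j]))
               for i in range(2) for j in range(len(labels))
               if abs(resid[i, j]) > crit]

    index = pd.Index(["focal", "background"])
    return ContingencyResult(
        observed=pd.DataFrame(obs, index=index, columns=labels),
        expected=pd.DataFrame(expected, index=index, columns=labels),
        statistic=float(statistic), dof=int(dof), pvalue=float(pvalue),
        residuals=pd.DataFrame(resid, index=index, columns=labels),
        flagged=flagged, alpha=alpha, monte_carlo=mc,
    )


def _monte_carlo_p(obs: np.ndarray, statistic: float, n_resamples: int, seed) -> float:
    rng = np.random.default_rng(seed)
    n = int(obs.sum())
    rows = obs.sum(axis=1) / n
    cols = obs.sum(axis=0) / n
    probs = np.outer(rows, cols).ravel()
    exceed = 0
    for _ in range(n_resamples):
        table = rng.multinomial(n, probs).reshape(obs.shape)
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            exceed += 1  # degenerate draw counts as extreme
            continue
        s, _, _, _ = stats.chi2_contingency(table, correction=False)
        if s >= statistic:
            exceed += 1
    return (1.0 + exceed) / (n_resamples + 1.0)


def tissue_composition_test(focal: pd.DataFrame, background: pd.DataFrame,
                            alpha: float = 0.05, **kw) -> ContingencyResult:
    """Is the tissue composition of derived-HF eQTLs different from the rest?"""
    return composition_test(
        focal["tissue"].value_counts(), background["tissue"].value_counts(),
        alpha=alpha, **kw,
    )


def category_composition_test(focal: pd.DataFrame, background: pd.DataFrame,
                              alpha: float = 0.05, **kw) -> ContingencyResult:
    """Same homogeneity design over consequence categories."""
    return composition_test(
        focal["consequence"].value_counts(), background["consequence"].value_counts(),
        alpha=alpha, **kw,
    )


@dataclass
class CorrelationResult:
    rho: float
    pvalue: float
    fit_coefficients: np.ndarray
    band_se: float
    fitted: pd.Series
    outliers: list


def sample_size_correlation(
    counts_per_tissue: pd.Series, samples_per_tissue: pd.Series
) -> CorrelationResult:
    """Spearman correlation of per-tissue eQTL count with sample size.

    Also fits a degree-2 polynomial (least squares) of count on sample size
    and reports tissues whose residual exceeds one residual standard error
    of the fit, the analogue of points outside a regression's standard-error
    band.
    """
    tissues = [t for t in counts_per_tissue.index if t in samples_per_tissue.index]
    if len(tissues) < 4:
        raise ValueError("need at least 4 tissues")
    y = counts_per_tissue.loc[tissues].to_numpy(dtype=float)
    x = samples_per_tissue.loc[tissues].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant counts: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    coef = np.polyfit(x, y, deg=2)
    fitted = np.polyval(coef, x)
    resid = y - fitted
    dof = max(len(tissues) - 3, 1)
    band = float(np.sqrt((resid ** 2).sum() / dof))
    outliers = [t for t, r in zip(tissues, resid) if abs(r) > band]
    return CorrelationResult(
        rho=float(rho), pvalue=float(p), fit_coefficients=coef, band_se=band,
        fitted=pd.Series(fitted, index=tissues), outliers=outliers,
    )


@dataclass
class SamplingTestResult:
    pvalue: float
    statistic: float
    observed_unique: pd.Series
    expected_unique: pd.Series
    n_resamples: int


def region_specific_sampling_test(
    clumped: pd.DataFrame,
    n_resamples: int = 100,
    seed: int = 0,
) -> SamplingTestResult:
    """Does any tissue draw more tissue-specific clumped eQTLs than expected?

    ``clumped`` holds one row per (index variant, tissue) clumped
    assignment (columns ``rsid``, ``tissue``). Tissue labels are permuted
    over the assignments (preserving per-tissue totals), the
    unique-to-one-tissue count vector is recomputed per resample, and the
    observed goodness-of-fit statistic against the resampling mean is
    compared with the permutation distribution of the same statistic
    (empirical p, +1 correction). Under exchangeable labels p is uniform.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = sorted(clumped["tissue"].unique())
    var_codes, _ = pd.factorize(clumped["rsid"], sort=True)
    lab_codes = pd.Categorical(clumped["tissue"], categories=tissues).codes
    n_vars, n_tissues = var_codes.max() + 1, len(tissues)

    def unique_counts(lab: np.ndarray) -> np.ndarray:
        hits = np.zeros((n_vars, n_tissues), dtype=bool)
        hits[var_codes, lab] = True
        per_var = hits.sum(axis=1)
        uniq_vars = per_var == 1
        return hits[uniq_vars].sum(axis=0).astype(float)

    observed = unique_counts(lab_codes)
    if observed.sum() == 0:
        warnings.warn("no tissue-specific clumped eQTLs; test skipped", stacklevel=2)
        empty = pd.Series(observed, index=tissues)
        return SamplingTestResult(pvalue=float("nan"), statistic=float("nan"),
                                  observed_unique=empty, expected_unique=empty,
                                  n_resamples=0)

    perms = np.empty((n_resamples, len(tissues)))
    for b in range(n_resamples):
        perms[b] = unique_counts(rng.permutation(lab_codes))
    expected = perms.mean(axis=0)
    safe = np.where(expected > 0, expected, np.nan)

    def gof(v: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            terms = (v - expected) ** 2 / safe
        return float(np.nansum(terms))

    stat_obs = gof(observed)
    stat_perm = np.array([gof(perms[b]) for b in range(n_resamples)])
    p = (1.0 + int((stat_perm >= stat_obs).sum())) / (n_resamples + 1.0)
    return SamplingTestResult(
        pvalue=float(p), statistic=stat_obs,
        observed_unique=pd.Series(observed, index=tissues),
        expected_unique=pd.Series(expected, index=tissues),
        n_resamples=n_resamples,
    )
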