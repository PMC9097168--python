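"""Linkage disequilibrium from haplotype panels and greedy p-value clumping.

The panel is a binary haplotype-by-variant matrix (1 = ALT allele). Pairwise
LD is the squared haplotype correlation

    r² = (p_AB − p_A·p_B)² / (p_A(1−p_A) · p_B(1−p_B))

and clumping follows the Plink convention: variants are sorted by ascending
association p-value, the best unassigned variant becomes an index, and every
unassigned variant within ``window_kb`` of it with r² at or above the
threshold joins its clump. The surviving index variants are the
LD-independent ("clumped") set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["HaplotypePanel", "Clump", "r2", "clump", "tissue_specific"]


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix with variant coordinates.

    Parameters
    ----------
    matrix
        ``(n_haplotypes, n_variants)`` array of 0/1 alleles (1 = ALT).
    chrom, pos, ids
        Per-variant chromosome label, 1-based position and identifier.
        Columns must be sorted by (chrom, pos).
    """

    matrix: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("haplotype matrix entries must be 0/1")
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if not (len(self.chrom) == len(self.pos) == len(self.ids) == self.matrix.shape[1]):
            raise ValueError("variant annotation length does not match matrix columns")
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def column(self, variant) -> np.ndarray:
        return self.matrix[:, self.loc(variant)]

    def loc(self, variant) -> int:
        """Column index of a variant given by id or integer position."""
        if isinstance(variant, (int, np.integer)):
            return int(variant)
        try:
            return self._index[variant]
        except KeyError:
            raise KeyError(f"variant {variant!r} not in panel") from None

    def allele_freq(self) -> np.ndarray:
        """ALT allele frequency per variant."""
        return self.matrix.mean(axis=0)


def r2(panel: HaplotypePanel, v1, v2) -> float:
    """Squared haplotype correlation between two panel variants.

    Raises
    ------
    ValueError
        If either variant is monomorphic in the panel (r² undefined).
    """
    a = panel.column(v1).astype(float)
    b = panel.column(v2).astype(float)
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        raise ValueError("r² undefined for a monomorphic variant")
    pab = np.mean(a * b)
    d = pab - pa * pb
    return float(d * d / (va * vb))


def _r2_to_index(panel: HaplotypePanel, idx: int, others: np.ndarray) -> np.ndarray:
    """Vectorised r² of one column against many; monomorphic columns get NaN."""
    a = panel.matrix[:, idx].astype(float)
    B = panel.matrix[:, others].astype(float)
    pa = a.mean()
    pb = B.mean(axis=0)
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    d = (a @ B) / len(a) - pa * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d * d / (va * vb)
    out[(vb == 0) | (va == 0)] = np.nan
    return out


@dataclass
class Clump:
    """One LD clump: an index variant and its absorbed members."""

    index_variant: str
    index_pval: float
    chrom: str
    pos: int
    members: pd.DataFrame  # columns: rsid, pos, pval, r2_with_index
    tissue: str | None = None

    @property
    def size(self) -> int:
        return 1 + len(self.members)


def clump(
    variants: pd.DataFrame,
    panel: HaplotypePanel,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    tissue: str | None = None,
) -> list[Clump]:
    """Greedy p-value-ordered LD clumping.

    Parameters
    ----------
    variants
        DataFrame with columns ``rsid``, ``chrom``, ``pos``, ``pval``.
    panel
        Haplotype panel supplying r². Variants absent from the panel (or
        monomorphic in it) cannot be clumped and are kept as singleton
        clumps, with a warning.
    r2_threshold
        Minimum r² with the index for a variant to join its clump.
    window_kb
        Maximum distance (kb) from the index variant.

    Returns
    -------
    list of :class:`Clump`, a partition of the input rows. Ties in p-value
    are broken by (chrom, pos) for determinism.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")

    df = variants.reset_index(drop=True).copy()
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy(), df["pval"].to_numpy()))

    in_panel = np.array([rs in panel._index for rs in df["rsid"]])
    panel_col = np.array([panel._index.get(rs, -1) for rs in df["rsid"]])
    freqs = panel.allele_freq()
    poly = in_panel.copy()
    poly[in_panel] &= (freqs[panel_col[in_panel]] > 0) & (freqs[panel_col[in_panel]] < 1)
    n_unclumpable = int((~poly).sum())
    if n_unclumpable:
        logger.warning(
            "%d variant(s) absent from or monomorphic in the LD panel; kept as singleton clumps",
            n_unclumpable,
        )

    assigned = np.zeros(len(df), dtype=bool)
    window_bp = window_kb * 1000.0
    clumps: list[Clump] = []
    chrom_arr = df["chrom"].to_numpy()
    pos_arr = df["pos"].to_numpy()

    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        member_rows = []
        if poly[i]:
            cand = np.flatnonzero(
                (~assigned)
                & poly
                & (chrom_arr == chrom_arr[i])
                & (np.abs(pos_arr - pos_arr[i]) <= window_bp)
            )
            if len(cand):
                r2s = _r2_to_index(panel, panel_col[i], panel_col[cand])
                keep = cand[np.nan_to_num(r2s, nan=-1.0) >= r2_threshold]
                keep_r2 = r2s[np.nan_to_num(r2s, nan=-1.0) >= r2_threshold]
                for j, rr in zip(keep, keep_r2):
                    assigned[j] = True
                    member_rows.append(
                        {
                            "rsid": df.at[j, "rsid"],
                            "pos": int(pos_arr[j]),
                            "pval": float(df.at[j, "pval"]),
                            "r2_with_index": float(rr),
                        }
                    )
        clumps.append(
            Clump(
                index_variant=df.at[i, "rsid"],
                index_pval=float(df.at[i, "pval"]),
                chrom=str(chrom_arr[i]),
                pos=int(pos_arr[i]),
                members=pd.DataFrame(
                    member_rows, columns=["rsid", "pos", "pval", "r2_with_index"]
                ),
                tissue=tissue,
            )
        )
    return clumps


def clumps_to_frame(clumps: list[Clump]) -> pd.DataFrame:
    """Flatten clumps into a table of index variants (one row per clump)."""
    return pd.DataFrame(
        {
            "rsid": [c.index_variant for c in clumps],
            "chrom": [c.chrom for c in clumps],
            "pos": [c.pos for c in clumps],
            "pval": [c.index_pval for c in clumps],
            "n_members": [len(c.members) for c in clumps],
            "tissue": [c.tissue for c in clumps],
        }
    )


def tissue_specific(clumped_by_tissue: dict[str, list[Clump] | set | list]) -> pd.Series:
    """Count index variants unique to exactly one tissue.

    Accepts per-tissue clump lists or plain collections of index rsids;
    returns a Series of tissue -> count of indices found in no other tissue.
    """
    sets: dict[str, set] = {}
    for tissue, val in clumped_by_tissue.items():
        if val and isinstance(next(iter(val), None), Clump):
            sets[tissue] = {c.index_variant for c in val}
        else:
            sets[tissue] = set(val)
    counts = {}
    for tissue, s in sets.items():
        others: set = set()
        for t2, s2 in sets.items():
            if t2 != tissue:
                others |= s2
        counts[tissue] = len(s - others)
    if sum(counts.values()) == 0:
        warnings.warn("no tissue-specific index variants found", stacklevel=2)
    return pd.Series(counts, name="n_tissue_specific")
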