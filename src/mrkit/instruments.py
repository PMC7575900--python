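"""Instrument selection: significance filtering, greedy LD clumping, and
Bonferroni enrichment of one exposure's instruments from another's hits.

Clumping is the standard greedy procedure: repeatedly take the remaining SNP
with the smallest p-value as an index SNP and discard every remaining SNP on
the same chromosome within the window whose squared LD correlation with the
index is at or above the threshold.  Ties in p are broken by (chrom, pos,
snp_id) so the result is deterministic and independent of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric pairwise r-squared over a SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {self.r2.shape} does not match {k} snp ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise FormatError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise FormatError("LD matrix diagonal is not 1")
        if k and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise FormatError("LD r2 values outside [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise FormatError("duplicate snp ids in LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise FormatError(f"{path}: LD matrix row and column ids differ")
        return cls([str(s) for s in df.index], df.to_numpy(float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


def select_significant(table: SumStatTable, p_threshold: float) -> SumStatTable:
    """Records with ``pval < p_threshold``, original order preserved."""
    if not (0.0 < p_threshold <= 1.0):
        raise ParameterError(f"p threshold {p_threshold} outside (0, 1]")
    keep = (table.df["pval"] < p_threshold).to_numpy()
    logger.info(
        "select_significant(%s): %d of %d records at p < %g",
        table.trait_label, int(keep.sum()), len(table), p_threshold,
    )
    return table.with_df(table.df[keep])


def clump(
    table: SumStatTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SumStatTable:
    """Greedy LD clumping; returns the index SNPs in the table's row order.

    SNPs absent from the LD matrix are dropped with a warning rather than
    assumed independent.  A SNP is removed when its r2 with a
    lower-or-equal-p index SNP on the same chromosome within ``window_kb``
    is >= ``r2_threshold``.
    """
    if not (0.0 <= r2_threshold < 1.0):
        raise ParameterError(f"r2 threshold {r2_threshold} outside [0, 1)")
    df = table.df
    in_panel = df["snp_id"].map(lambda s: s in ld).to_numpy()
    if not in_panel.all():
        dropped = df["snp_id"][~in_panel].tolist()
        logger.warning(
            "clump(%s): dropping %d SNP(s) absent from LD panel: %s",
            table.trait_label, len(dropped), dropped[:10],
        )
        df = df[in_panel]
    if len(df) == 0:
        return table.with_df(df)

    order = df.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).index
    window_bp = window_kb * 1_000
    alive = {i: True for i in order}
    kept: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        chrom_i = df.at[i, "chrom"]
        pos_i = df.at[i, "pos"]
        sid_i = df.at[i, "snp_id"]
        for j in order:
            if not alive[j]:
                continue
            if df.at[j, "chrom"] != chrom_i:
                continue
            if abs(df.at[j, "pos"] - pos_i) > window_bp:
                continue
            if ld.lookup(sid_i, df.at[j, "snp_id"]) >= r2_threshold:
                alive[j] = False
    kept_ids = set(df.loc[kept, "snp_id"])
    logger.info(
        "clump(%s): %d index SNP(s) from %d at r2 < %g",
        table.trait_label, len(kept_ids), len(df), r2_threshold,
    )
    return table.with_df(table.df[table.df["snp_id"].isin(kept_ids)])


def enrich_instruments(
    base_instruments: SumStatTable,
    candidate_snps: SumStatTable,
    target_exposure: SumStatTable,
    n_tests: int,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SumStatTable:
    """Admit candidate SNPs associated with the target exposure at the
    Bonferroni level 0.05 / ``n_tests``, union with the base instruments, and
    clump the union.

    Records for the final set are drawn from ``target_exposure`` (falling
    back to the base table for instruments the exposure table lacks), so the
    returned betas are the target exposure's.
    """
    if n_tests < 1:
        raise ParameterError(f"n_tests {n_tests} must be >= 1")
    threshold = 0.05 / n_tests
    target = target_exposure.df.set_index("snp_id")
    admitted = [
        s for s in candidate_snps.snp_ids
        if s in target.index and float(target.at[s, "pval"]) < threshold
    ]
    logger.info(
        "enrich_instruments: %d of %d candidates pass p < %g",
        len(admitted), len(candidate_snps), threshold,
    )
    union_ids = list(dict.fromkeys(base_instruments.snp_ids + admitted))
    rows = []
    for s in union_ids:
        if s in target.index:
            rows.append(target.loc[s:s].reset_index())
        else:
            rows.append(
                base_instruments.df[base_instruments.df["snp_id"] == s]
            )
    df = pd.concat(rows, ignore_index=True) if rows else target_exposure.df.iloc[:0]
    union = target_exposure.with_df(df)
    return clump(union, ld, r2_threshold=r2_threshold, window_kb=window_kb)


def extract_snps(
    table: SumStatTable, snp_ids: Sequence[str]
) -> tuple[SumStatTable, list[str]]:
    """Subset by id, preserving the order of ``snp_ids``; the second element
    lists the requested ids not present in the table."""
    idx = table.df.set_index("snp_id")
    present = [s for s in snp_ids if s in idx.index]
    missing = [s for s in snp_ids if s not in idx.index]
    if missing:
        logger.warning("extract_snps: %d id(s) not found: %s", len(missing), missing)
    df = idx.loc[present].reset_index() if present else table.df.iloc[:0]
    return table.with_df(df), missing
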