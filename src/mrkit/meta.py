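"""Fixed-effect inverse-variance meta-analysis of GWAS summary tables.

Effect sizes are combined with weights 1/se^2 (the effect-size weighting
scheme, not sample-size z-weighting): per shared SNP

    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2)
    se_meta   = (sum(1 / se_i^2)) ** -0.5

with a normal p-value, summed sample size and an n-weighted mean effect
allele frequency.  Tables after the first are aligned to the first table's
allele convention; allele-incompatible SNPs are dropped with a log entry.
By default the analysed set is the union of SNPs across tables (with a per-
SNP cohort-count column); ``mode='intersect'`` restricts to shared SNPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .harmonise import align_alleles
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)


def meta_fixed(
    tables: list[SumStatTable],
    mode: str = "union",
    trait_label: str | None = None,
    palindrome_policy: str = "infer",
    eaf_tolerance: float = 0.08,
) -> SumStatTable:
    """Fixed-effect meta-analysis of two or more summary tables."""
    if len(tables) < 2:
        raise ParameterError(f"meta-analysis requires >= 2 tables, got {len(tables)}")
    if mode not in ("union", "intersect"):
        raise ParameterError(f"unknown mode {mode!r}")

    # reference allele convention per SNP: first table that carries the SNP
    ref: dict[str, dict] = {}
    per_snp: dict[str, list[dict]] = {}
    order: list[str] = []
    n_dropped = 0
    for table in tables:
        for row in table.df.itertuples(index=False):
            s = row.snp_id
            if s not in ref:
                ref[s] = {
                    "chrom": str(row.chrom), "pos": int(row.pos),
                    "effect_allele": row.effect_allele,
                    "other_allele": row.other_allele,
                    "eaf": float(row.eaf),
                }
                per_snp[s] = []
                order.append(s)
                beta, eaf = float(row.beta), float(row.eaf)
            else:
                r = ref[s]
                beta, eaf, action = align_alleles(
                    r["effect_allele"], r["other_allele"], r["eaf"],
                    row.effect_allele, row.other_allele,
                    float(row.beta), float(row.eaf),
                    palindrome_policy, eaf_tolerance,
                )
                if action.startswith("dropped"):
                    n_dropped += 1
                    logger.info("meta_fixed: %s dropped from %s (%s)",
                                s, table.trait_label, action)
                    continue
            per_snp[s].append(
                {"beta": beta, "se": float(row.se), "n": float(row.n), "eaf": eaf}
            )

    n_tables = len(tables)
    rows = []
    for s in order:
        contribs = per_snp[s]
        if not contribs:
            continue
        if mode == "intersect" and len(contribs) < n_tables:
            continue
        w = np.array([1.0 / c["se"] ** 2 for c in contribs])
        betas = np.array([c["beta"] for c in contribs])
        ns = np.array([c["n"] for c in contribs])
        eafs = np.array([c["eaf"] for c in contribs])
        sw = w.sum()
        beta_meta = float((w * betas).sum() / sw)
        se_meta = float(sw**-0.5)
        z = beta_meta / se_meta
        p = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
        rows.append(
            {
                "snp_id": s, "chrom": ref[s]["chrom"], "pos": ref[s]["pos"],
                "effect_allele": ref[s]["effect_allele"],
                "other_allele": ref[s]["other_allele"],
                "eaf": float((ns * eafs).sum() / ns.sum()),
                "beta": beta_meta, "se": se_meta, "pval": p,
                "n": float(ns.sum()), "n_cohorts": len(contribs),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval", "n", "n_cohorts"],
    )
    label = trait_label or f"meta({'+'.join(t.trait_label for t in tables)})"
    logger.info(
        "meta_fixed: %d SNPs analysed (%s mode), %d record(s) dropped as incompatible",
        len(df), mode, n_dropped,
    )
    return SumStatTable(label, tables[0].trait_type, df)
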