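"""GWAS summary-statistics data model, file I/O and record-level transforms.

A :class:`SumStatTable` wraps a pandas DataFrame with one row per SNP and a
canonical column set.  Files are plain tab-delimited text with a header; the
mapping from file column names to the canonical names is configurable, with a
compact default dialect (``snp, chr, pos, ea, oa, eaf, beta, se, pval, n,
ncase_frac``).

Binary traits come in two flavours.  ``binary-lmm`` tables carry per-allele
effects estimated by a linear (mixed) model on the 0/1 phenotype; these are
converted to the log-odds scale with :func:`lmm_beta_to_logor`, the
first-order expansion ``beta / (mu * (1 - mu))`` where ``mu`` is the case
fraction.  ``binary-logor`` tables already carry log odds ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
TRAIT_TYPES = ("quantitative", "binary-lmm", "binary-logor")

#: canonical column order used by :func:`write_sumstats`
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "case_fraction",
]

#: default file-header -> canonical-name mapping
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "snp_id",
    "chr": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "ncase_frac": "case_fraction",
}

_REQUIRED = [c for c in CANONICAL_COLUMNS if c != "case_fraction"]


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not a single nucleotide"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not a single nucleotide"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if not (self.se > 0.0):
            raise ValidationError(f"{self.snp_id}: se {self.se} must be > 0")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if not (self.n > 0):
            raise ValidationError(f"{self.snp_id}: sample size {self.n} must be > 0")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ValidationError(
                f"{self.snp_id}: case fraction {self.case_fraction} outside (0, 1)"
            )

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SumStatTable:
    """An ordered collection of summary-statistic records for one trait.

    ``df`` holds the canonical columns; ``case_fraction`` is present only for
    binary traits.  ``snp_id`` values are unique; row order is meaningful and
    preserved by every operation.
    """

    trait_label: str
    trait_type: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ParameterError(
                f"trait_type {self.trait_type!r} not one of {TRAIT_TYPES}"
            )
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Sequence[SumStatRecord], trait_label: str, trait_type: str
    ) -> "SumStatTable":
        rows = [
            {
                "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pval,
                "n": r.n, "case_fraction": r.case_fraction,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        if trait_type == "quantitative":
            df = df.drop(columns=["case_fraction"])
        return cls(trait_label, trait_type, df)

    @classmethod
    def from_arrays(
        cls,
        trait_label: str,
        trait_type: str,
        *,
        snp_id: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
        effect_allele: Sequence[str],
        other_allele: Sequence[str],
        eaf: Sequence[float],
        beta: Sequence[float],
        se: Sequence[float],
        pval: Sequence[float],
        n: Sequence[float],
        case_fraction: Sequence[float] | float | None = None,
    ) -> "SumStatTable":
        data = {
            "snp_id": list(snp_id), "chrom": list(chrom), "pos": list(pos),
            "effect_allele": list(effect_allele), "other_allele": list(other_allele),
            "eaf": np.asarray(eaf, float), "beta": np.asarray(beta, float),
            "se": np.asarray(se, float), "pval": np.asarray(pval, float),
            "n": np.asarray(n, float),
        }
        if case_fraction is not None:
            cf = np.asarray(case_fraction, float)
            data["case_fraction"] = np.broadcast_to(cf, (len(data["snp_id"]),)).copy()
        return cls(trait_label, trait_type, pd.DataFrame(data))

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"{self.trait_label}: missing columns {missing}")
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise FormatError(
                f"{self.trait_label}: duplicate snp_id values {sorted(set(dup))}"
            )
        if self.trait_type.startswith("binary"):
            if "case_fraction" not in df.columns or df["case_fraction"].isna().any():
                raise ValidationError(
                    f"{self.trait_label}: binary trait requires case_fraction on all records"
                )
        if len(df) == 0:
            return
        checks = {
            "effect and other allele identical": df["effect_allele"] == df["other_allele"],
            "non-ACGT allele": ~(
                df["effect_allele"].isin(VALID_ALLELES)
                & df["other_allele"].isin(VALID_ALLELES)
            ),
            "eaf outside (0,1)": ~((df["eaf"] > 0) & (df["eaf"] < 1)),
            "se not > 0": ~(df["se"] > 0),
            "p-value outside (0,1]": ~((df["pval"] > 0) & (df["pval"] <= 1)),
            "n not > 0": ~(df["n"] > 0),
        }
        if self.trait_type.startswith("binary"):
            cf = df["case_fraction"]
            checks["case fraction outside (0,1)"] = ~((cf > 0) & (cf < 1))
        problems = []
        for what, bad in checks.items():
            for idx in df.index[bad.fillna(True)]:
                problems.append(f"row {idx} ({df.at[idx, 'snp_id']}): {what}")
        if problems:
            raise ValidationError(
                f"{self.trait_label}: {len(problems)} invalid record(s): "
                + "; ".join(problems[:20])
            )

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[SumStatRecord]:
        has_cf = "case_fraction" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield SumStatRecord(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                pval=float(row.pval), n=float(row.n),
                case_fraction=(
                    None if not has_cf or pd.isna(row.case_fraction)
                    else float(row.case_fraction)
                ),
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def subset(self, mask_or_ids) -> "SumStatTable":
        """New table restricted to a boolean mask or an id collection
        (table order preserved)."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(mask_or_ids) and isinstance(
            next(iter(mask_or_ids)), (bool, np.bool_)
        ):
            sub = self.df[np.asarray(mask_or_ids, bool)]
        else:
            wanted = set(mask_or_ids)
            sub = self.df[self.df["snp_id"].isin(wanted)]
        return replace(self, df=sub.reset_index(drop=True))

    def with_df(self, df: pd.DataFrame) -> "SumStatTable":
        return replace(self, df=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_sumstats(
    path,
    *,
    trait_label: str,
    trait_type: str = "quantitative",
    column_map: Mapping[str, str] | None = None,
) -> SumStatTable:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps file header names to canonical field names; the
    default dialect is :data:`DEFAULT_COLUMN_MAP`.  Alleles are upper-cased.
    Rows failing validation raise :class:`ValidationError` naming the row.
    """
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(path, sep="\t", dtype={c: str for c in cmap})
    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    got = set(present.values())
    need = set(_REQUIRED)
    if trait_type.startswith("binary"):
        need.add("case_fraction")
    missing = sorted(need - got)
    if missing:
        raise FormatError(
            f"{path}: mapped columns for {missing} not found in header {list(raw.columns)}"
        )
    df = raw[list(present)].rename(columns=present)
    for col in ("eaf", "beta", "se", "pval", "n", "case_fraction"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                idx = int(df.index[bad][0])
                raise FormatError(
                    f"{path}: non-numeric {col} at row {idx} "
                    f"(snp {df.at[idx, 'snp_id']}): {df.at[idx, col]!r}"
                )
            df[col] = coerced.astype(float)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    table = SumStatTable(trait_label, trait_type, df)
    logger.info("read %d records for %s from %s", len(table), trait_label, path)
    return table


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table in the canonical column order, tab-delimited, full float
    precision (round-trips exactly through :func:`read_sumstats`)."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    out = table.df[cols].rename(
        columns={dst: src for src, dst in DEFAULT_COLUMN_MAP.items()}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def filter_maf(table: SumStatTable, maf_min: float) -> SumStatTable:
    """Retain records with minor-allele frequency strictly above ``maf_min``."""
    if not (0.0 <= maf_min < 0.5):
        raise ParameterError(f"maf_min {maf_min} outside [0, 0.5)")
    maf = np.minimum(table.df["eaf"], 1.0 - table.df["eaf"])
    keep = maf > maf_min
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_maf(%s): removed %d of %d records at MAF <= %g",
            table.trait_label, removed, len(table), maf_min,
        )
    return table.with_df(table.df[keep.to_numpy()])


def lmm_beta_to_logor(beta: float, se: float, mu: float) -> tuple[float, float]:
    """First-order conversion of a 0/1-scale effect to a log odds ratio.

    For a binary trait with case fraction ``mu``, a per-allele effect ``beta``
    estimated by linear (mixed-model) regression on the 0/1 phenotype maps to
    the log-odds scale as ``beta / (mu * (1 - mu))``; the standard error
    scales by the same factor, so the z-score is preserved exactly.
    """
    if not (0.0 < mu < 1.0):
        raise ParameterError(f"case fraction mu {mu} outside (0, 1)")
    if isinstance(se, (int, float)) and not se > 0:
        raise ParameterError(f"se {se} must be > 0")
    scale = mu * (1.0 - mu)
    return beta / scale, se / scale


def table_lmm_to_logor(table: SumStatTable) -> SumStatTable:
    """Apply :func:`lmm_beta_to_logor` record-wise; ``binary-lmm`` becomes
    ``binary-logor``.  P-values are untouched (z-scores are invariant)."""
    if table.trait_type != "binary-lmm":
        raise ParameterError(
            f"{table.trait_label}: trait_type is {table.trait_type!r}, expected 'binary-lmm'"
        )
    df = table.df.copy()
    scale = df["case_fraction"] * (1.0 - df["case_fraction"])
    df["beta"] = df["beta"] / scale
    df["se"] = df["se"] / scale
    return SumStatTable(table.trait_label, "binary-logor", df)
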