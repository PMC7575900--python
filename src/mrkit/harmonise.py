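"""Align exposure and outcome summary statistics to one effect-allele
convention.

For each SNP shared by id, the outcome record is expressed on the exposure's
effect allele.  Four situations arise:

* same allele pair, same orientation -> kept as is (``aligned``);
* same allele pair, swapped -> outcome beta negated, eaf complemented
  (``flipped``);
* complementary allele pair (the outcome was reported on the opposite
  strand) -> alleles complemented first (``strand-corrected``);
* palindromic SNPs (A/T or G/C), where strand cannot be resolved from the
  alleles: under policy ``drop`` they are removed; under ``infer`` the two
  allele frequencies decide the orientation, and SNPs whose frequency on
  either side lies within ``eaf_tolerance`` of 0.5 are removed as ambiguous.

Any other allele combination is dropped as incompatible.  Every disposition
is recorded per SNP in the action log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoOverlapError, ParameterError
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "aligned", "flipped", "strand-corrected",
    "dropped-palindromic", "dropped-incompatible",
)


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def align_alleles(
    ea_ref: str,
    oa_ref: str,
    eaf_ref: float,
    ea: str,
    oa: str,
    beta: float,
    eaf: float,
    palindrome_policy: str = "infer",
    eaf_tolerance: float = 0.08,
) -> tuple[float, float, str]:
    """Express one record (``ea/oa/beta/eaf``) on the reference effect allele.

    Returns ``(beta, eaf, action)``; for dropped actions beta and eaf are NaN.
    """
    if palindrome_policy not in ("drop", "infer"):
        raise ParameterError(f"unknown palindrome policy {palindrome_policy!r}")
    nan = float("nan")
    if is_palindromic(ea_ref, oa_ref):
        if {ea, oa} != {ea_ref, oa_ref}:
            return nan, nan, "dropped-incompatible"
        if palindrome_policy == "drop":
            return nan, nan, "dropped-palindromic"
        if abs(eaf_ref - 0.5) <= eaf_tolerance or abs(eaf - 0.5) <= eaf_tolerance:
            return nan, nan, "dropped-palindromic"
        if ea == ea_ref:
            b, f, action = beta, eaf, "aligned"
        else:
            b, f, action = -beta, 1.0 - eaf, "flipped"
        if (eaf_ref - 0.5) * (f - 0.5) < 0:
            # allele labels disagree with frequencies: opposite strand
            b, f, action = -b, 1.0 - f, "strand-corrected"
        return b, f, action
    if (ea, oa) == (ea_ref, oa_ref):
        return beta, eaf, "aligned"
    if (ea, oa) == (oa_ref, ea_ref):
        return -beta, 1.0 - eaf, "flipped"
    cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
    if (cea, coa) == (ea_ref, oa_ref):
        return beta, eaf, "strand-corrected"
    if (cea, coa) == (oa_ref, ea_ref):
        return -beta, 1.0 - eaf, "strand-corrected"
    return nan, nan, "dropped-incompatible"


@dataclass
class HarmonisedSet:
    """Per-SNP exposure/outcome effects on one shared effect allele.

    ``df`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    gamma_hat, se_gamma, Gamma_hat, se_Gamma, eaf_exposure, eaf_outcome.
    ``actions`` maps every shared SNP to its disposition.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame = field(repr=False)
    actions: pd.DataFrame = field(repr=False)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def gamma_hat(self) -> np.ndarray:
        return self.df["gamma_hat"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(float)

    @property
    def Gamma_hat(self) -> np.ndarray:
        return self.df["Gamma_hat"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.df["se_Gamma"].to_numpy(float)

    def subset(self, mask) -> "HarmonisedSet":
        return HarmonisedSet(
            self.exposure_label, self.outcome_label,
            self.df[np.asarray(mask, bool)].reset_index(drop=True),
            self.actions,
        )

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_arrays(
        cls,
        gamma_hat,
        se_gamma,
        Gamma_hat,
        se_Gamma,
        snp_ids=None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> "HarmonisedSet":
        """Assemble a set directly from aligned effect arrays (useful for
        simulation studies that skip allele bookkeeping)."""
        gamma_hat = np.asarray(gamma_hat, float)
        k = len(gamma_hat)
        ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(k)]
        df = pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": ["1"] * k,
                "pos": np.arange(1, k + 1),
                "effect_allele": ["A"] * k,
                "other_allele": ["G"] * k,
                "gamma_hat": gamma_hat,
                "se_gamma": np.asarray(se_gamma, float),
                "Gamma_hat": np.asarray(Gamma_hat, float),
                "se_Gamma": np.asarray(se_Gamma, float),
                "eaf_exposure": [np.nan] * k,
                "eaf_outcome": [np.nan] * k,
            }
        )
        actions = pd.DataFrame({"snp_id": ids, "action": ["aligned"] * k})
        return cls(exposure_label, outcome_label, df, actions)


def align_table(
    reference: SumStatTable,
    other: SumStatTable,
    palindrome_policy: str = "infer",
    eaf_tolerance: float = 0.08,
) -> tuple[SumStatTable, pd.DataFrame]:
    """Re-express every shared SNP of ``other`` on ``reference``'s effect
    alleles; SNPs dropped by policy are removed.  Returns the aligned table
    (restricted to shared, kept SNPs in reference order) and the action log."""
    ref = reference.df.set_index("snp_id")
    oth = other.df.set_index("snp_id")
    shared = [s for s in reference.snp_ids if s in oth.index]
    rows, log = [], []
    for s in shared:
        r, o = ref.loc[s], oth.loc[s]
        beta, eaf, action = align_alleles(
            r["effect_allele"], r["other_allele"], float(r["eaf"]),
            o["effect_allele"], o["other_allele"], float(o["beta"]), float(o["eaf"]),
            palindrome_policy, eaf_tolerance,
        )
        log.append({"snp_id": s, "action": action})
        if action.startswith("dropped"):
            continue
        row = o.copy()
        row["effect_allele"] = r["effect_allele"]
        row["other_allele"] = r["other_allele"]
        row["beta"] = beta
        row["eaf"] = eaf
        row["snp_id"] = s
        rows.append(row)
    actions = pd.DataFrame(log, columns=["snp_id", "action"])
    if rows:
        df = pd.DataFrame(rows).reset_index(drop=True)[other.df.columns]
    else:
        df = other.df.iloc[:0]
    return other.with_df(df), actions


def harmonise(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindrome_policy: str = "infer",
    eaf_tolerance: float = 0.08,
) -> HarmonisedSet:
    """Build the harmonised exposure/outcome set over shared SNPs."""
    shared = set(exposure.snp_ids) & set(outcome.snp_ids)
    if not shared:
        raise NoOverlapError(
            f"no SNPs shared between {exposure.trait_label} and {outcome.trait_label}"
        )
    aligned, actions = align_table(exposure, outcome, palindrome_policy, eaf_tolerance)
    exp = exposure.df.set_index("snp_id")
    out = aligned.df.set_index("snp_id")
    kept = [s for s in exposure.snp_ids if s in out.index]
    df = pd.DataFrame(
        {
            "snp_id": kept,
            "chrom": [str(exp.at[s, "chrom"]) for s in kept],
            "pos": [int(exp.at[s, "pos"]) for s in kept],
            "effect_allele": [exp.at[s, "effect_allele"] for s in kept],
            "other_allele": [exp.at[s, "other_allele"] for s in kept],
            "gamma_hat": [float(exp.at[s, "beta"]) for s in kept],
            "se_gamma": [float(exp.at[s, "se"]) for s in kept],
            "Gamma_hat": [float(out.at[s, "beta"]) for s in kept],
            "se_Gamma": [float(out.at[s, "se"]) for s in kept],
            "eaf_exposure": [float(exp.at[s, "eaf"]) for s in kept],
            "eaf_outcome": [float(out.at[s, "eaf"]) for s in kept],
        }
    )
    counts = actions["action"].value_counts().to_dict()
    logger.info(
        "harmonise(%s vs %s): %d shared, dispositions %s",
        exposure.trait_label, outcome.trait_label, len(actions), counts,
    )
    return HarmonisedSet(exposure.trait_label, outcome.trait_label, df, actions)
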