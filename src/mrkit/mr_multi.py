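"""Multivariable Mendelian randomisation: direct effects of several exposures
on one outcome, each conditioning on the others.

The model regresses the per-SNP outcome effects on the matrix of per-SNP
exposure effects (no intercept for the IVW variant, free intercept for the
Egger variant) with weights 1/se_Gamma^2.  Coefficient m is the direct
effect of exposure m net of the pathways through the other exposures — with
an upstream->downstream causal chain between exposures this separates the
direct effect from the mediated (total) effect that univariable MR reports.

Conditional instrument strength follows the Sanderson–Windmeijer
construction: each exposure's betas are regressed on the other exposures'
betas and the residual-based Q statistic is normalised to an F scale; the
exact normalisation used here is Q_x / (k - m + 1) with an upper-tail
chi-square(k - m + 1) p-value for the null of no conditional signal (small p
= strong conditional instruments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    InsufficientInstrumentsError,
    ParameterError,
)
from .harmonise import align_table
from .instruments import LDMatrix, clump
from .mr_uni import Z95, MRResult, HeterogeneityResult
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class MVMRInput:
    """Aligned per-SNP effects for k SNPs x m exposures and one outcome."""

    snp_ids: list[str]
    exposure_betas: np.ndarray = field(repr=False)  # (k, m)
    exposure_ses: np.ndarray = field(repr=False)    # (k, m)
    outcome_betas: np.ndarray = field(repr=False)   # (k,)
    outcome_ses: np.ndarray = field(repr=False)     # (k,)
    exposure_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_betas = np.asarray(self.outcome_betas, float)
        self.outcome_ses = np.asarray(self.outcome_ses, float)
        k, m = self.exposure_betas.shape
        if not self.exposure_labels:
            self.exposure_labels = [f"exposure{i + 1}" for i in range(m)]
        if self.exposure_ses.shape != (k, m):
            raise ParameterError("exposure_ses shape mismatch")
        if len(self.outcome_betas) != k or len(self.outcome_ses) != k:
            raise ParameterError("outcome arrays do not match SNP count")
        if len(self.snp_ids) != k:
            raise ParameterError("snp_ids do not match SNP count")
        if np.any(self.exposure_ses <= 0) or np.any(self.outcome_ses <= 0):
            raise ParameterError("all standard errors must be > 0")

    @property
    def k(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def m(self) -> int:
        return self.exposure_betas.shape[1]


def build_mvmr_input(
    instrument_union: SumStatTable,
    exposure_tables: list[SumStatTable],
    outcome: SumStatTable,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    palindrome_policy: str = "infer",
    eaf_tolerance: float = 0.08,
) -> MVMRInput:
    """Assemble the MVMR design from summary tables.

    The instrument union is clumped jointly (priority: minimum p across the
    exposure tables), every table is aligned to the first exposure's allele
    convention, and SNPs missing from any table are dropped with a log entry.
    """
    if len(exposure_tables) < 2:
        raise ParameterError("MVMR requires >= 2 exposures")
    exp_idx = [t.df.set_index("snp_id") for t in exposure_tables]
    union = instrument_union.df.copy()
    # joint clump priority: the best (smallest) p across exposures
    min_p = [
        min(
            (float(ix.at[s, "pval"]) for ix in exp_idx if s in ix.index),
            default=1.0,
        )
        for s in union["snp_id"]
    ]
    union["pval"] = min_p
    union_t = instrument_union.with_df(union)
    if ld is not None:
        union_t = clump(union_t, ld, r2_threshold=r2_threshold, window_kb=window_kb)

    ref = exposure_tables[0]
    aligned_exp = [ref.subset(union_t.snp_ids)]
    for t in exposure_tables[1:]:
        at, _ = align_table(ref, t, palindrome_policy, eaf_tolerance)
        aligned_exp.append(at)
    aligned_out, _ = align_table(ref, outcome, palindrome_policy, eaf_tolerance)

    idxs = [t.df.set_index("snp_id") for t in aligned_exp]
    out_idx = aligned_out.df.set_index("snp_id")
    kept, dropped = [], []
    for s in union_t.snp_ids:
        if all(s in ix.index for ix in idxs) and s in out_idx.index:
            kept.append(s)
        else:
            dropped.append(s)
    if dropped:
        logger.info(
            "build_mvmr_input: dropped %d SNP(s) missing from some table: %s",
            len(dropped), dropped[:10],
        )
    m = len(exposure_tables)
    if len(kept) <= m:
        raise InsufficientInstrumentsError(
            f"{len(kept)} SNPs for {m} exposures after assembly"
        )
    eb = np.array([[float(ix.at[s, "beta"]) for ix in idxs] for s in kept])
    es = np.array([[float(ix.at[s, "se"]) for ix in idxs] for s in kept])
    ob = np.array([float(out_idx.at[s, "beta"]) for s in kept])
    os_ = np.array([float(out_idx.at[s, "se"]) for s in kept])
    return MVMRInput(
        kept, eb, es, ob, os_, [t.trait_label for t in exposure_tables]
    )


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    zero = np.all(X == 0, axis=0)
    if zero.any():
        bad = [labels[i] for i in np.flatnonzero(zero)]
        raise CollinearityError(f"exposure(s) with all-zero instrument effects: {bad}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"exposure-beta matrix is rank deficient over {labels}"
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int):
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / df_resid if df_resid > 0 else 1.0
    cov = xtwx_inv * max(1.0, sigma2)
    return coef, cov, resid


def mvmr_ivw(x: MVMRInput) -> list[MRResult]:
    """Weighted multivariable regression of outcome on exposure betas without
    intercept; coefficient m is the direct effect of exposure m."""
    k, m = x.k, x.m
    if k <= m:
        raise InsufficientInstrumentsError(f"{k} SNPs for {m} exposures")
    _check_rank(x.exposure_betas, x.exposure_labels)
    w = 1.0 / x.outcome_ses**2
    coef, cov, _ = _wls(x.exposure_betas, x.outcome_betas, w, k - m)
    results = []
    for i, label in enumerate(x.exposure_labels):
        b, se = float(coef[i]), float(np.sqrt(cov[i, i]))
        p = 2 * stats.norm.sf(abs(b / se))
        results.append(
            MRResult(f"mvmr_ivw[{label}]", b, se, b - Z95 * se, b + Z95 * se, p, k)
        )
    return results


def mvmr_egger(
    x: MVMRInput, orientation_exposure: str | None = None
) -> tuple[list[MRResult], HeterogeneityResult]:
    """MVMR-Egger: as :func:`mvmr_ivw` with a free intercept, after orienting
    every SNP so its beta on the orientation exposure is >= 0.

    Inference is standard WLS t(k - m - 1) with the estimated residual scale
    (no flooring), so the intercept test holds its nominal level under the
    no-pleiotropy null."""
    k, m = x.k, x.m
    if k <= m + 1:
        raise InsufficientInstrumentsError(
            f"MVMR-Egger needs k > m + 1; got k={k}, m={m}"
        )
    labels = x.exposure_labels
    j = labels.index(orientation_exposure) if orientation_exposure else 0
    flip = x.exposure_betas[:, j] < 0
    eb = x.exposure_betas.copy()
    ob = x.outcome_betas.copy()
    eb[flip] *= -1
    ob[flip] *= -1
    _check_rank(eb, labels)
    w = 1.0 / x.outcome_ses**2
    X = np.column_stack([np.ones(k), eb])
    df_resid = k - m - 1
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ ob)
    resid = ob - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / df_resid
    cov = xtwx_inv * sigma2
    from .mr_uni import _t_pval

    tq = float(stats.t.ppf(0.975, df_resid))
    results = []
    for i, label in enumerate(labels):
        b, se = float(coef[i + 1]), float(np.sqrt(cov[i + 1, i + 1]))
        p = _t_pval(b, se, df_resid)
        results.append(
            MRResult(f"mvmr_egger[{label}]", b, se, b - tq * se, b + tq * se, p, k)
        )
    int_b, int_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    q_val = float(np.sum(w * resid**2))
    het = HeterogeneityResult(
        Q=q_val, df=df_resid, pval=float(stats.chi2.sf(q_val, df_resid)),
        egger_intercept=int_b, intercept_se=int_se,
        intercept_pval=_t_pval(int_b, int_se, df_resid),
    )
    return results, het


def conditional_f(x: MVMRInput, exposure: str) -> tuple[float, float]:
    """Conditional instrument strength of one exposure given the others
    (Sanderson–Windmeijer style).

    The exposure's betas are regressed on the other exposures' betas
    (weights 1 / se of the exposure's betas, no intercept); the residual Q
    statistic is Q_x = sum(resid^2 / se^2), the reported statistic is
    F = Q_x / (k - m + 1), and the p-value is the chi-square(k - m + 1)
    upper tail of Q_x — the null being no conditional instrument signal, so
    a SMALL p supports instrument relevance.
    """
    labels = x.exposure_labels
    if exposure not in labels:
        raise ParameterError(f"unknown exposure {exposure!r}; have {labels}")
    k, m = x.k, x.m
    j = labels.index(exposure)
    t = x.exposure_betas[:, j]
    st = x.exposure_ses[:, j]
    others = np.delete(x.exposure_betas, j, axis=1)
    w = 1.0 / st**2
    if others.shape[1] == 0 or np.allclose(others, 0):
        resid = t
    else:
        XtW = others.T * w
        try:
            delta = np.linalg.solve(XtW @ others, XtW @ t)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("other-exposure matrix is singular") from exc
        resid = t - others @ delta
    q_x = float(np.sum(w * resid**2))
    dof = k - m + 1
    f = q_x / dof
    p = float(stats.chi2.sf(q_x, dof))
    return f, p


def mvmr_results_table(results: list[MRResult]) -> pd.DataFrame:
    rows = [r.to_dict() for r in results]
    return pd.DataFrame(rows)
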