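"""Seeded generator of two-sample GWAS summary statistics with known causal
structure, plus a small individual-level cohort simulator.

The summary-statistics model mirrors the instrumental-variable setting in
which two-sample MR estimators are defined.  For m exposures and k SNPs:

* true SNP-exposure effects gamma_1j ~ Normal(0, gamma_sd^2) for the first
  exposure; for a second exposure gamma_2j = chain_theta * gamma_1j + own
  effects, encoding an upstream->downstream biomarker chain (e.g. IL-6
  driving CRP production);
* pleiotropic direct effects alpha_j are zero (``none``), centred
  (``balanced``) or shifted (``directional``) normal draws;
* true SNP-outcome effects Gamma_j = sum_m beta_m * gamma_mj + alpha_j on
  the log-odds scale for a binary outcome;
* observed betas add independent sampling noise in the exposure and outcome
  samples, with the variance-standardised closed form
  se = 1 / sqrt(2 * n * maf * (1 - maf)) for quantitative traits and
  se = 1 / sqrt(2 * n * maf * (1 - maf) * mu * (1 - mu)) on the log-odds
  scale for a binary outcome with case fraction mu.

Under ``pleiotropy="none"`` the InSIDE condition holds trivially (alpha is
identically zero).  LD is injected at the level of true effects: members of
a configured block share the index SNP's causal signal attenuated by
sqrt(r2), and the realised LD matrix is block-structured with the configured
within-block r2.

Default sample sizes and the outcome case fraction follow the motivating
study design: outcome GWAS n = 153,560 with 4.37% cases (self-harm; 2.26%
for the stricter suicide-attempt outcome), upstream exposure (IL-6
meta-analysis) n = 8,296, downstream exposure (CRP GWAS) n = 48,164.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .instruments import LDMatrix
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pleiotropy:
    """Direct SNP-outcome effect regime: ``none``, ``balanced(sd)`` or
    ``directional(mean, sd)``."""

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ParameterError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ParameterError("balanced pleiotropy has mean 0 by definition")
        if self.sd < 0:
            raise ParameterError("pleiotropy sd must be >= 0")

    @classmethod
    def parse(cls, spec) -> "Pleiotropy":
        """Accept 'none', {'kind': 'balanced', 'sd': ...}, or a Pleiotropy."""
        if isinstance(spec, Pleiotropy):
            return spec
        if spec in (None, "none"):
            return cls("none")
        if isinstance(spec, dict):
            return cls(spec.get("kind", "none"), float(spec.get("mean", 0.0)),
                       float(spec.get("sd", 0.0)))
        raise ParameterError(f"cannot parse pleiotropy spec {spec!r}")


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth configuration of a synthetic two-sample MR study."""

    n_snps: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    beta_causal: tuple[float, ...] = (0.0, -0.08)
    gamma_sd: float = 0.05
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    pleiotropy_frac: float = 1.0  # fraction of SNPs that are invalid instruments
    chain_theta: float = 0.5
    n_exposure: tuple[float, ...] = (8_296, 48_164)
    n_outcome: float = 153_560
    outcome_case_fraction: float = 0.0437
    ld_blocks: tuple[tuple[int, float], ...] = ()
    outcome_scale: str = "logor"  # 'logor' or 'lmm'
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range {self.maf_range} not within (0, 0.5]")
        m = len(self.beta_causal)
        n_exp = self.n_exposure if isinstance(self.n_exposure, tuple) else (self.n_exposure,)
        if len(n_exp) != m:
            raise ParameterError(
                f"{m} causal effects but {len(n_exp)} exposure sample sizes"
            )
        if any(n < 2 for n in n_exp) or self.n_outcome < 2:
            raise ParameterError("sample sizes must be >= 2")
        if not (0.0 < self.outcome_case_fraction < 1.0):
            raise ParameterError("outcome case fraction outside (0, 1)")
        if self.outcome_scale not in ("logor", "lmm"):
            raise ParameterError(f"unknown outcome scale {self.outcome_scale!r}")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ParameterError("ld_blocks cover more SNPs than n_snps")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")
        if not (0.0 < self.pleiotropy_frac <= 1.0):
            raise ParameterError("pleiotropy_frac outside (0, 1]")

    @property
    def n_exposures(self) -> int:
        return len(self.beta_causal)

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "pleiotropy" in d:
            d["pleiotropy"] = Pleiotropy.parse(d["pleiotropy"])
        for key in ("beta_causal", "n_exposure", "maf_range"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
            elif key in d and key in ("beta_causal", "n_exposure"):
                d[key] = (d[key],)
        if "ld_blocks" in d and d["ld_blocks"] is not None:
            d["ld_blocks"] = tuple((int(s), float(r)) for s, r in d["ld_blocks"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one realisation, for recovery tests."""

    gamma: np.ndarray = field(repr=False)   # (k, m) true SNP-exposure effects
    alpha: np.ndarray = field(repr=False)   # (k,) true pleiotropic effects
    beta: tuple[float, ...] = ()
    ld: LDMatrix | None = None


def _block_assignment(scenario: SimScenario) -> list[tuple[list[int], float]]:
    """SNP-index groups for each configured LD block (remaining SNPs are
    singletons, i.e. independent)."""
    blocks = []
    cursor = 0
    for size, r2 in scenario.ld_blocks:
        blocks.append((list(range(cursor, cursor + size)), r2))
        cursor += size
    for i in range(cursor, scenario.n_snps):
        blocks.append(([i], 0.0))
    return blocks


def _se_quantitative(n: float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _se_binary_logor(n: float, maf: np.ndarray, mu: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf) * mu * (1.0 - mu))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]  # non-palindromic


def _make_table(
    label: str,
    trait_type: str,
    snp_ids: list[str],
    chrom: list[str],
    pos: np.ndarray,
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
    case_fraction: float | None = None,
) -> SumStatTable:
    return SumStatTable.from_arrays(
        label, trait_type,
        snp_id=snp_ids, chrom=chrom, pos=pos,
        effect_allele=[a for a, _ in alleles],
        other_allele=[b for _, b in alleles],
        eaf=eaf, beta=beta, se=se, pval=_pvals(beta, se),
        n=np.full(len(snp_ids), float(n)),
        case_fraction=case_fraction,
    )


def simulate_two_sample(
    scenario: SimScenario,
) -> tuple[list[SumStatTable], SumStatTable, LDMatrix, SimTruth]:
    """Generate exposure table(s), an outcome table, the realised LD matrix
    and the ground truth for one scenario.  Identical seeds give identical
    output."""
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    k, m = scenario.n_snps, scenario.n_exposures
    mu = scenario.outcome_case_fraction

    snp_ids = [f"rs{i + 1}" for i in range(k)]
    blocks = _block_assignment(scenario)
    chrom = np.empty(k, dtype=object)
    for b, (members, _) in enumerate(blocks):
        for i in members:
            chrom[i] = str(b % 22 + 1)
    pos = np.arange(1, k + 1) * 100_000
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(k)]
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, k)
    eaf = maf  # effect allele taken as the minor allele

    # true effects: blocks share the index signal attenuated by sqrt(r2)
    gamma = np.zeros((k, m))
    own = rng.normal(0.0, scenario.gamma_sd, size=(k, m))
    for members, r2 in blocks:
        idx = members[0]
        for col in range(m):
            gamma[idx, col] = own[idx, col]
            for j in members[1:]:
                gamma[j, col] = np.sqrt(r2) * own[idx, col]
    if m >= 2:
        # causal chain: exposure 1 feeds exposure 2
        gamma[:, 1] = scenario.chain_theta * gamma[:, 0] + gamma[:, 1]

    pl = scenario.pleiotropy
    alpha = np.zeros(k)
    if pl.kind != "none":
        n_invalid = int(round(scenario.pleiotropy_frac * k))
        invalid = rng.choice(k, size=n_invalid, replace=False)
        draws = rng.normal(pl.mean, pl.sd, n_invalid)
        if pl.kind == "directional":
            # directional pleiotropy is defined on the exposure-increasing
            # orientation; re-express it on the stored effect allele
            draws = draws * np.sign(gamma[invalid, 0])
        alpha[invalid] = draws
    Gamma = gamma @ np.asarray(scenario.beta_causal) + alpha

    # realised LD matrix
    r2_mat = np.eye(k)
    for members, r2 in blocks:
        for a in members:
            for b in members:
                if a != b:
                    r2_mat[a, b] = r2
    ld = LDMatrix(snp_ids, r2_mat)

    n_exp = scenario.n_exposure if isinstance(scenario.n_exposure, tuple) else (scenario.n_exposure,)
    exposures = []
    for col in range(m):
        se = _se_quantitative(n_exp[col], maf)
        obs = gamma[:, col] + scenario.noise_scale * se * rng.standard_normal(k)
        exposures.append(
            _make_table(
                f"exposure{col + 1}", "quantitative", snp_ids, list(chrom), pos,
                alleles, eaf, obs, se, n_exp[col],
            )
        )

    se_out = _se_binary_logor(scenario.n_outcome, maf, mu)
    obs_out = Gamma + scenario.noise_scale * se_out * rng.standard_normal(k)
    if scenario.outcome_scale == "lmm":
        scale = mu * (1.0 - mu)
        outcome = _make_table(
            "outcome", "binary-lmm", snp_ids, list(chrom), pos, alleles, eaf,
            obs_out * scale, se_out * scale, scenario.n_outcome, mu,
        )
    else:
        outcome = _make_table(
            "outcome", "binary-logor", snp_ids, list(chrom), pos, alleles, eaf,
            obs_out, se_out, scenario.n_outcome, mu,
        )
    truth = SimTruth(gamma=gamma, alpha=alpha, beta=tuple(scenario.beta_causal), ld=ld)
    return exposures, outcome, ld, truth


@dataclass
class CohortData:
    """Individual-level cohort with per-SNP linear and logistic summaries."""

    genotypes: np.ndarray = field(repr=False)  # (n, k) 0/1/2
    phenotype: np.ndarray = field(repr=False)  # (n,) 0/1
    liability: np.ndarray = field(repr=False)
    linear: SumStatTable = field(repr=False)   # binary-lmm style
    logistic: SumStatTable = field(repr=False)  # binary-logor


def simulate_cohort(scenario: SimScenario, n_individuals: int) -> CohortData:
    """Simulate genotypes and a liability-threshold binary phenotype, and run
    per-SNP linear (0/1 outcome) and logistic regressions.

    Genotypes are Hardy-Weinberg draws at the scenario MAFs; the liability is
    the genetic score (first-exposure effects applied to standardised
    genotypes) plus standard-normal noise, thresholded so the expected case
    fraction equals the scenario's.  The linear summaries emulate what a
    linear mixed model reports for a 0/1 trait; the logistic summaries are
    the per-SNP log odds ratios used as the transformation oracle.
    """
    if n_individuals > 100_000:
        raise ParameterError("cohort simulator is desk-scale: n <= 100000")
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(2)[1])
    k = scenario.n_snps
    mu = scenario.outcome_case_fraction
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, k)
    geno = rng.binomial(2, maf, size=(n_individuals, k)).astype(float)
    gamma = rng.normal(0.0, scenario.gamma_sd, k)
    std = np.sqrt(2.0 * maf * (1.0 - maf))
    geno_std = (geno - 2.0 * maf) / std
    score = geno_std @ gamma
    liab = score + rng.standard_normal(n_individuals)
    threshold = stats.norm.ppf(1.0 - mu) * np.sqrt(1.0 + float(np.sum(gamma**2)))
    y = (liab > threshold).astype(float)
    n_cases = int(y.sum())
    if n_cases < 10:
        raise DegenerateInputError(
            f"degenerate phenotype: only {n_cases} case(s) at case fraction {mu}"
        )
    case_frac = n_cases / n_individuals

    lin_beta = np.empty(k)
    lin_se = np.empty(k)
    log_beta = np.empty(k)
    log_se = np.empty(k)
    yc = y - y.mean()
    for j in range(k):
        g = geno[:, j]
        gc = g - g.mean()
        sxx = float(gc @ gc)
        b = float(gc @ yc) / sxx
        resid = yc - b * gc
        s2 = float(resid @ resid) / (n_individuals - 2)
        lin_beta[j] = b
        lin_se[j] = np.sqrt(s2 / sxx)
        fit = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        log_beta[j] = fit.params[1]
        log_se[j] = fit.bse[1]

    snp_ids = [f"rs{i + 1}" for i in range(k)]
    chrom = ["1"] * k
    pos = np.arange(1, k + 1) * 100_000
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(k)]
    linear = _make_table(
        "cohort-linear", "binary-lmm", snp_ids, chrom, pos, alleles, maf,
        lin_beta, lin_se, n_individuals, case_frac,
    )
    logistic = _make_table(
        "cohort-logistic", "binary-logor", snp_ids, chrom, pos, alleles, maf,
        log_beta, log_se, n_individuals, case_frac,
    )
    return CohortData(geno, y, liab, linear, logistic)
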