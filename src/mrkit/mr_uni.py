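"""Univariable two-sample Mendelian-randomisation estimators and
pleiotropy/heterogeneity diagnostics.

All estimators consume a :class:`~mrkit.harmonise.HarmonisedSet` with per-SNP
exposure effects gamma_hat (se_gamma) and outcome effects Gamma_hat
(se_Gamma) on one shared effect allele, and return the causal effect on the
scale of the outcome betas (a log odds ratio for binary outcomes).

Implemented methods
-------------------
wald          per-SNP ratio Gamma/gamma, first-order SE
ivw           inverse-variance-weighted mean of ratios == WLS of Gamma on
              gamma through the origin with weights 1/se_Gamma^2; default
              variance model is multiplicative random effects with the
              residual scale floored at 1 (never shrinks below fixed effect)
egger         WLS with a free intercept after orienting gamma >= 0; the
              intercept estimates average directional pleiotropy; t(k-2)
              inference
weighted_median   interpolated weighted median of ratios; parametric
              bootstrap SE
simple_mode / weighted_mode  kernel-density mode of the ratios (normal
              kernel, modified-Silverman bandwidth); parametric bootstrap SE

Diagnostics: Cochran's Q over the ratio estimates, the Egger intercept test,
the mean instrument F statistic, and funnel-plot coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientInstrumentsError,
    ParameterError,
)
from .harmonise import HarmonisedSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal-effect estimate on the log-OR scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — exponentiated point estimate and CI."""
        return (np.exp(self.beta), np.exp(self.ci_low), np.exp(self.ci_high))

    def to_dict(self) -> dict:
        or_, lo, hi = self.or_scale
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "n_snps": self.n_snps, "or": or_, "or_ci_low": lo, "or_ci_high": hi,
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q and/or the Egger intercept test."""

    Q: float | None = None
    df: int | None = None
    pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


def _t_pval(est: float, se: float, df: int) -> float:
    """Two-sided t p-value, defined for exact fits (se = 0)."""
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2 * stats.t.sf(abs(est / se), df))


def _ratios(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their ratio weights gamma^2 / se_Gamma^2."""
    g, G, sG = h.gamma_hat, h.Gamma_hat, h.se_Gamma
    if np.any(g == 0):
        raise DegenerateInputError("zero exposure effect: Wald ratio undefined")
    return G / g, g**2 / sG**2


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float) -> MRResult:
    """Single-SNP causal estimate: the outcome effect divided by the exposure
    effect, with the first-order SE ``se_Gamma / |gamma|``."""
    if gamma == 0:
        raise DegenerateInputError("gamma = 0: Wald ratio undefined")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult("wald", beta, se, beta - Z95 * se, beta + Z95 * se, p, 1)


def ivw(h: HarmonisedSet, variance_model: str = "multiplicative_re") -> MRResult:
    """Inverse-variance-weighted estimate.

    Equivalent formulations: the weighted mean of per-SNP ratios with weights
    gamma^2/se_Gamma^2, or WLS of Gamma on gamma through the origin with
    weights 1/se_Gamma^2.  ``multiplicative_re`` scales the fixed-effect SE
    by the residual scale when it exceeds 1.
    """
    if variance_model not in ("fixed", "multiplicative_re"):
        raise ParameterError(f"unknown variance model {variance_model!r}")
    k = h.n_snps
    if k == 0:
        raise InsufficientInstrumentsError("empty harmonised set")
    g, G, sG = h.gamma_hat, h.Gamma_hat, h.se_Gamma
    if k == 1:
        r = wald_ratio(g[0], h.se_gamma[0], G[0], sG[0])
        return MRResult("ivw", r.beta, r.se, r.ci_low, r.ci_high, r.pval, 1)
    w = 1.0 / sG**2
    swg2 = float(np.sum(w * g**2))
    if swg2 == 0:
        raise DegenerateInputError("all exposure effects are zero")
    beta = float(np.sum(w * g * G)) / swg2
    se = swg2 ** -0.5
    if variance_model == "multiplicative_re":
        resid = G - beta * g
        sigma2 = float(np.sum(w * resid**2)) / (k - 1)
        se *= max(1.0, np.sqrt(sigma2))
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult("ivw", beta, se, beta - Z95 * se, beta + Z95 * se, p, k)


def egger(h: HarmonisedSet) -> tuple[MRResult, HeterogeneityResult]:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept, after orienting every SNP to gamma >= 0.

    The slope is the causal estimate under the InSIDE condition; the
    intercept estimates average directional pleiotropy.  Inference is the
    standard WLS t(k-2) inference with the estimated residual scale (no
    flooring: the intercept test is exact at its nominal level under the
    no-pleiotropy null).
    """
    k = h.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 SNPs, got {k}")
    g, G, sG = h.gamma_hat.copy(), h.Gamma_hat.copy(), h.se_Gamma
    flip = g < 0
    g[flip] *= -1
    G[flip] *= -1
    w = 1.0 / sG**2
    X = np.column_stack([np.ones(k), g])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ G)
    resid = G - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    cov = xtwx_inv * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tq = float(stats.t.ppf(0.975, k - 2))
    p_slope = _t_pval(slope, se_slope, k - 2)
    p_int = _t_pval(intercept, se_int, k - 2)
    result = MRResult(
        "egger", slope, se_slope,
        slope - tq * se_slope, slope + tq * se_slope, float(p_slope), k,
    )
    q_egger = float(np.sum(w * resid**2))
    het = HeterogeneityResult(
        Q=q_egger, df=k - 2, pval=float(stats.chi2.sf(q_egger, k - 2)),
        egger_intercept=intercept, intercept_se=se_int, intercept_pval=float(p_int),
    )
    return result, het


def weighted_median(
    h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None
) -> MRResult:
    """Weighted median of the per-SNP ratios (consistent when >50% of the
    weight comes from valid instruments); SE by seeded parametric bootstrap."""
    k = h.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 SNPs, got {k}")
    if seed is None:
        raise ParameterError("weighted_median requires an explicit seed")
    beta = _weighted_median_point(h.gamma_hat, h.Gamma_hat, h.se_Gamma)
    se = _bootstrap_se(h, n_boot, seed, _weighted_median_point)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MRResult("weighted_median", beta, se, beta - Z95 * se, beta + Z95 * se, p, k)


def _weighted_median_point(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> float:
    b = G / g
    w = g**2 / sG**2
    order = np.argsort(b, kind="mergesort")
    b, w = b[order], w[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2
    if cum[0] >= 0.5:
        return float(b[0])
    i = int(np.searchsorted(cum, 0.5))
    if i >= len(b):
        return float(b[-1])
    frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(b[i - 1] + frac * (b[i] - b[i - 1]))


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    # modified Silverman rule on the ratio estimates
    s = float(np.std(b, ddof=1))
    mad = float(stats.median_abs_deviation(b, scale="normal"))
    spread = min(s, mad) if mad > 0 else s
    return phi * 0.9 * spread * len(b) ** (-1 / 5)


def _kde_mode(b: np.ndarray, w: np.ndarray, bandwidth: float) -> float:
    if bandwidth == 0:
        return float(b[0])
    grid = np.linspace(b.min() - 3 * bandwidth, b.max() + 3 * bandwidth, 512)
    dens = (w[:, None] * np.exp(-0.5 * ((grid - b[:, None]) / bandwidth) ** 2)).sum(0)
    return float(grid[int(np.argmax(dens))])


def _simple_mode_point(g, G, sG, phi=1.0):
    b = G / g
    return _kde_mode(b, np.full(len(b), 1.0 / len(b)), _mode_bandwidth(b, phi))


def _weighted_mode_point(g, G, sG, phi=1.0):
    b = G / g
    w = g**2 / sG**2
    return _kde_mode(b, w / w.sum(), _mode_bandwidth(b, phi))


def mode_estimators(
    h: HarmonisedSet, phi: float = 1.0, n_boot: int = 1000, seed: int | None = None
) -> tuple[MRResult, MRResult]:
    """Simple and weighted mode-based estimates.

    The ratio estimates are smoothed with a normal kernel whose bandwidth is
    ``phi * 0.9 * min(SD, normalised MAD) * k^(-1/5)``; the causal estimate
    is the density argmax, unweighted for the simple mode and weighted by
    inverse ratio variance for the weighted mode.  If every ratio is
    identical the common value is returned directly.
    """
    k = h.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"mode estimators require >= 3 SNPs, got {k}")
    if seed is None:
        raise ParameterError("mode_estimators requires an explicit seed")
    results = []
    for name, fn in (("simple_mode", _simple_mode_point), ("weighted_mode", _weighted_mode_point)):
        point = lambda g, G, sG, _fn=fn: _fn(g, G, sG, phi)
        beta = point(h.gamma_hat, h.Gamma_hat, h.se_Gamma)
        se = _bootstrap_se(h, n_boot, seed, point)
        p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
        results.append(
            MRResult(name, beta, se, beta - Z95 * se, beta + Z95 * se, p, k)
        )
    return results[0], results[1]


def _bootstrap_se(h: HarmonisedSet, n_boot: int, seed: int, point_fn) -> float:
    """Parametric bootstrap: redraw gamma_hat and Gamma_hat from normal
    sampling distributions centred on the observed values."""
    rng = np.random.default_rng(seed)
    g, sg, G, sG = h.gamma_hat, h.se_gamma, h.Gamma_hat, h.se_Gamma
    k = len(g)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        gb = g + sg * rng.standard_normal(k)
        Gb = G + sG * rng.standard_normal(k)
        gb[gb == 0] = np.finfo(float).tiny  # guard: ratio undefined at 0
        draws[i] = point_fn(gb, Gb, sG)
    return float(np.std(draws, ddof=1))


def cochran_q(h: HarmonisedSet) -> HeterogeneityResult:
    """Cochran's Q over the per-SNP ratio estimates with ratio weights
    gamma^2/se_Gamma^2; chi-square(k-1) reference distribution."""
    k = h.n_snps
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires >= 2 SNPs, got {k}")
    b, w = _ratios(h)
    b_ivw = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - b_ivw) ** 2))
    return HeterogeneityResult(Q=Q, df=k - 1, pval=float(stats.chi2.sf(Q, k - 1)))


def mean_f_statistic(h: HarmonisedSet) -> float:
    """Mean per-SNP instrument-strength F statistic gamma^2/se_gamma^2;
    values below ~10 signal weak-instrument bias."""
    if h.n_snps < 1:
        raise InsufficientInstrumentsError("empty harmonised set")
    return float(np.mean(h.gamma_hat**2 / h.se_gamma**2))


def funnel_data(h: HarmonisedSet, mr_results: list[MRResult] | None = None) -> pd.DataFrame:
    """Per-SNP Wald ratios against precision, for funnel-plot asymmetry
    checks; reference lines at each supplied method estimate."""
    if h.n_snps == 0:
        return pd.DataFrame(columns=["snp_id", "ratio", "precision", "kind"])
    g, G, sG = h.gamma_hat, h.Gamma_hat, h.se_Gamma
    rows = pd.DataFrame(
        {
            "snp_id": h.df["snp_id"],
            "ratio": G / g,
            "precision": np.abs(g) / sG,
            "kind": "snp",
        }
    )
    if mr_results:
        refs = pd.DataFrame(
            {
                "snp_id": [r.method for r in mr_results],
                "ratio": [r.beta for r in mr_results],
                "precision": np.nan,
                "kind": "reference",
            }
        )
        rows = pd.concat([rows, refs], ignore_index=True)
    return rows


def all_univariable(
    h: HarmonisedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    phi: float = 1.0,
    variance_model: str = "multiplicative_re",
) -> tuple[list[MRResult], dict]:
    """Run every estimator applicable at the available instrument count, plus
    diagnostics.  Returns (results, diagnostics dict)."""
    results: list[MRResult] = []
    diagnostics: dict = {"n_snps": h.n_snps, "mean_f": mean_f_statistic(h)}
    if h.n_snps == 1:
        results.append(
            wald_ratio(h.gamma_hat[0], h.se_gamma[0], h.Gamma_hat[0], h.se_Gamma[0])
        )
        return results, diagnostics
    results.append(ivw(h, variance_model))
    q = cochran_q(h)
    diagnostics["cochran_q"] = {"Q": q.Q, "df": q.df, "pval": q.pval}
    if h.n_snps >= 3:
        eg, het = egger(h)
        results.append(eg)
        diagnostics["egger_intercept"] = {
            "intercept": het.egger_intercept,
            "se": het.intercept_se,
            "pval": het.intercept_pval,
        }
        results.append(weighted_median(h, n_boot=n_boot, seed=seed))
        simple, weighted = mode_estimators(h, phi=phi, n_boot=n_boot, seed=seed)
        results.extend([simple, weighted])
    return results, diagnostics
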