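"""Univariable estimators: closed-form checks, algebraic identities,
invariances and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from mrkit.errors import (
    DegenerateInputError,
    InsufficientInstrumentsError,
    ParameterError,
)
from mrkit.mr_uni import (
    cochran_q,
    egger,
    funnel_data,
    ivw,
    mean_f_statistic,
    mode_estimators,
    wald_ratio,
    weighted_median,
)

from conftest import hset


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.02, 0.0, 0.01).beta == 0.0

    def test_joint_sign_flip_symmetry(self):
        a = wald_ratio(0.1, 0.02, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.02, -0.05, 0.01)
        assert a.beta == b.beta and a.se == b.se

    def test_zero_gamma_rejected(self):
        with pytest.raises(DegenerateInputError):
            wald_ratio(0.0, 0.02, 0.05, 0.01)

    def test_or_scale_is_exp(self):
        r = wald_ratio(0.1, 0.02, 0.05, 0.01)
        or_, lo, hi = r.or_scale
        assert or_ == pytest.approx(np.exp(r.beta))
        assert lo <= or_ <= hi


class TestIVW:
    def test_closed_form_example(self):
        h = hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01])
        r = ivw(h, variance_model="fixed")
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(np.sqrt(1 / 500))
        assert cochran_q(h).Q == pytest.approx(0.0, abs=1e-24)
        # residuals are zero, so the floored random-effects SE coincides
        assert ivw(h).se == pytest.approx(np.sqrt(1 / 500))

    def test_single_snp_reduces_to_wald(self):
        h = hset([0.1], [0.02], [0.05], [0.01])
        r = ivw(h)
        w = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert (r.beta, r.se) == (w.beta, w.se)

    def test_equals_weighted_mean_of_ratios(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 30))
            g = rng.normal(0, 0.1, k)
            g[g == 0] = 0.01
            sG = rng.uniform(0.005, 0.05, k)
            G = rng.normal(0, 0.05, k)
            h = hset(g, rng.uniform(0.005, 0.02, k), G, sG)
            wls = ivw(h).beta
            ratios = G / g
            w = g**2 / sG**2
            assert abs(wls - np.sum(w * ratios) / np.sum(w)) < 1e-10

    def test_multiplicative_re_never_below_fixed(self, rng):
        g = rng.normal(0, 0.1, 20)
        h = hset(g, 0.01 * np.ones(20), rng.normal(0, 0.1, 20), 0.02 * np.ones(20))
        assert ivw(h).se >= ivw(h, "fixed").se

    def test_order_and_sign_invariance(self, rng):
        k = 12
        g = rng.normal(0, 0.1, k)
        sg = rng.uniform(0.005, 0.02, k)
        G = rng.normal(0, 0.05, k)
        sG = rng.uniform(0.005, 0.05, k)
        base = ivw(hset(g, sg, G, sG))
        perm = rng.permutation(k)
        assert ivw(hset(g[perm], sg[perm], G[perm], sG[perm])).beta == pytest.approx(base.beta)
        flip = rng.choice([-1.0, 1.0], k)
        assert ivw(hset(g * flip, sg, G * flip, sG)).beta == pytest.approx(base.beta)

    def test_all_zero_gamma_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ivw(hset([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.01, 0.01]))

    def test_unknown_variance_model(self):
        with pytest.raises(ParameterError):
            ivw(hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01]), "bogus")


class TestEgger:
    def test_exact_linear_fit(self):
        g = np.array([0.1, 0.2, 0.3])
        G = 0.01 + 0.5 * g
        r, het = egger(hset(g, [0.01] * 3, G, [0.01] * 3))
        assert r.beta == pytest.approx(0.5, abs=1e-12)
        assert het.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert r.pval < 1e-10  # exact fit up to floating point

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))

    def test_orientation_invariance(self, rng):
        k = 10
        g = rng.normal(0, 0.1, k)
        sg = rng.uniform(0.005, 0.02, k)
        G = 0.01 + 0.4 * g + rng.normal(0, 0.01, k)
        sG = rng.uniform(0.01, 0.03, k)
        base, base_het = egger(hset(g, sg, G, sG))
        flip = rng.choice([-1.0, 1.0], k)
        flipped, flip_het = egger(hset(g * flip, sg, G * flip, sG))
        assert flipped.beta == pytest.approx(base.beta)
        assert flip_het.egger_intercept == pytest.approx(base_het.egger_intercept)

    def test_intercept_test_nominal_level(self):
        # no pleiotropy: intercept t-test is exact, rejection near 5%
        rng = np.random.default_rng(42)
        k, reps, rej = 30, 400, 0
        g = np.abs(rng.normal(0, 0.05, k))
        sG = np.full(k, 0.02)
        for _ in range(reps):
            G = 0.1 * g + sG * rng.standard_normal(k)
            _, het = egger(hset(g, np.full(k, 0.007), G, sG))
            rej += het.intercept_pval < 0.05
        assert 0.02 < rej / reps < 0.09


class TestMedianAndModes:
    def test_all_ratios_equal(self):
        g = np.array([0.1, 0.2, 0.4])
        G = 0.7 * g
        h = hset(g, [0.01] * 3, G, [0.01] * 3)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.7)
        simple, weighted = mode_estimators(h, n_boot=50, seed=1)
        assert simple.beta == pytest.approx(0.7)
        assert weighted.beta == pytest.approx(0.7)

    def test_symmetric_interpolation(self):
        # equal weights, ratios 0.4/0.5/0.6: cumulative weight hits 0.5 at
        # the middle ratio
        g = np.array([1.0, 1.0, 1.0])
        G = np.array([0.4, 0.5, 0.6])
        h = hset(g, [0.01] * 3, G, [0.01] * 3)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.5)

    def test_simple_mode_finds_majority_cluster(self):
        g = np.ones(4)
        G = np.array([0.5, 0.5, 0.5, 1.5])
        h = hset(g, [0.01] * 4, G, [0.01] * 4)
        simple, _ = mode_estimators(h, n_boot=50, seed=2)
        # KDE argmax on a fine grid must sit near the 0.5 cluster
        assert abs(simple.beta - 0.5) < 0.05

    def test_seed_required(self):
        h = hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        with pytest.raises(ParameterError):
            weighted_median(h, n_boot=10, seed=None)
        with pytest.raises(ParameterError):
            mode_estimators(h, n_boot=10, seed=None)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0, 0.1, 10)
        h = hset(g, [0.01] * 10, 0.3 * g + rng.normal(0, 0.01, 10), [0.02] * 10)
        a = weighted_median(h, n_boot=100, seed=5)
        b = weighted_median(h, n_boot=100, seed=5)
        assert a.se == b.se


class TestDiagnostics:
    def test_cochran_hand_example(self):
        # two ratios 0.4 and 0.6, each with ratio variance 0.01
        g = np.array([1.0, 1.0])
        G = np.array([0.4, 0.6])
        sG = np.array([0.1, 0.1])  # ratio variance = (sG/g)^2 = 0.01
        h = hset(g, [0.01] * 2, G, sG)
        q = cochran_q(h)
        assert q.Q == pytest.approx(2.0)
        assert q.df == 1
        assert q.pval == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-6)
        assert q.pval == pytest.approx(0.157, abs=0.001)

    def test_identical_ratios_give_zero_q(self):
        g = np.array([0.1, 0.2, 0.5])
        h = hset(g, [0.01] * 3, 0.3 * g, [0.01] * 3)
        assert cochran_q(h).Q == pytest.approx(0.0, abs=1e-20)

    def test_mean_f(self):
        assert mean_f_statistic(hset([0.1], [0.02], [0.0], [0.01])) == pytest.approx(25)
        assert mean_f_statistic(
            hset([0.1, 0.1], [0.02, 0.02], [0.0, 0.0], [0.01, 0.01])
        ) == pytest.approx(25)

    def test_funnel_rows(self):
        h = hset([0.1], [0.02], [0.05], [0.01])
        fd = funnel_data(h)
        assert len(fd) == 1
        assert fd.at[0, "ratio"] == pytest.approx(0.5)
        assert fd.at[0, "precision"] == pytest.approx(10.0)
        empty = funnel_data(h.subset([False]))
        assert len(empty) == 0

    def test_funnel_symmetry_under_no_pleiotropy(self):
        rng = np.random.default_rng(8)
        k = 300
        g = np.abs(rng.normal(0.05, 0.02, k)) + 0.02
        sG = np.full(k, 0.02)
        G = 0.1 * g + sG * rng.standard_normal(k)
        fd = funnel_data(hset(g, np.full(k, 0.005), G, sG))
        slope = np.polyfit(fd["precision"], fd["ratio"], 1)[0]
        # regression of ratio on precision has slope ~ 0 for symmetric data
        assert abs(slope) < 0.02
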