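"""The five p-value engines: oracles, invariants and cross-consistency."""

import numpy as np
import pytest
from scipy import stats

from triarm import (
    CGF,
    BootstrapConfig,
    Margin,
    RateTriple,
    StatisticKind,
    TrialCounts,
    p_approx_unconditional,
    p_asymptotic,
    p_bootstrap,
    p_exact_unconditional,
    p_saddlepoint,
    tail_probability,
)
from triarm.model import rmle
from triarm.pvalues import LatticeTooLarge, _lr_tail, cgf_eval, saddlepoint_root
from triarm.statistics import statistic, statistic_lattice

from conftest import random_counts


class TestAsymptotic:
    def test_zero_statistic_gives_half(self, theta06):
        c = TrialCounts(5, 10, 5, 10, 5, 10)
        assert p_asymptotic(c, theta06, StatisticKind.WALD).value == 0.5

    def test_decreasing_in_observed_statistic(self, theta06):
        # larger x_T -> larger contrast -> larger T -> smaller p
        pvals = [
            p_asymptotic(TrialCounts(x, 12, 5, 12, 2, 12), theta06, StatisticKind.WALD).value
            for x in range(4, 12)
        ]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))


class TestCGF:
    def test_cumulant_identities_at_zero(self, theta06):
        rates = RateTriple(0.3, 0.45, 0.15)
        cg = CGF(theta06, (12, 15, 9), rates)
        K, d1, d2 = cgf_eval(cg, 0.0)
        assert K == 0.0
        assert d1 == pytest.approx(0.3 - 0.6 * 0.45 - 0.4 * 0.15, abs=1e-14)
        expected_var = (
            0.3 * 0.7 / 12 + 0.36 * 0.45 * 0.55 / 15 + 0.16 * 0.15 * 0.85 / 9
        )
        assert d2 == pytest.approx(expected_var, abs=1e-14)

    def test_derivatives_match_finite_differences(self, theta06):
        rng = np.random.default_rng(12)
        h = 1e-6
        for _ in range(5):
            rates = RateTriple(*rng.uniform(0.1, 0.9, size=3))
            cg = CGF(theta06, (8, 11, 7), rates)
            for t in (-0.5, 0.5):
                K_p, _, _ = cgf_eval(cg, t + h)
                K_m, _, _ = cgf_eval(cg, t - h)
                _, d1, _ = cgf_eval(cg, t)
                assert (K_p - K_m) / (2 * h) == pytest.approx(d1, abs=1e-6)

    def test_matches_enumerated_mgf(self):
        # direct oracle: log E[exp(t * psi_hat)] by summing over the lattice
        m = Margin(0.5)
        n = 4
        rates = RateTriple(0.5, 0.5, 0.5)
        cg = CGF(m, (n, n, n), rates)
        k = np.arange(n + 1)
        xT, xR, xP = np.meshgrid(k, k, k, indexing="ij")
        w = (
            stats.binom.pmf(k, n, 0.5)[:, None, None]
            * stats.binom.pmf(k, n, 0.5)[None, :, None]
            * stats.binom.pmf(k, n, 0.5)[None, None, :]
        )
        psi_hat = xT / n - 0.5 * xR / n - 0.5 * xP / n
        for t in (-2.0, -0.7, 0.3, 1.5):
            direct = np.log(np.sum(w * np.exp(t * psi_hat)))
            K, _, _ = cgf_eval(cg, t)
            assert K == pytest.approx(direct, abs=1e-12)


class TestSaddlepointRoot:
    def test_mean_maps_to_zero(self, theta06):
        cg = CGF(theta06, (20, 20, 20), RateTriple(0.4, 0.5, 0.25))
        _, mean, _ = cgf_eval(cg, 0.0)
        assert saddlepoint_root(cg, mean) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip(self, theta06):
        rng = np.random.default_rng(13)
        for _ in range(5):
            cg = CGF(theta06, (15, 10, 20), RateTriple(*rng.uniform(0.2, 0.8, size=3)))
            _, target, _ = cgf_eval(cg, 0.3)
            assert saddlepoint_root(cg, target) == pytest.approx(0.3, abs=1e-9)

    def test_out_of_range_threshold_rejected(self, theta06):
        cg = CGF(theta06, (10, 10, 10), RateTriple(0.4, 0.5, 0.25))
        with pytest.raises(ValueError):
            saddlepoint_root(cg, 1.0)
        with pytest.raises(ValueError):
            saddlepoint_root(cg, 1.5)


class TestSaddlepoint:
    def test_wald_and_score_tails_coincide(self, dyspepsia_counts, theta06):
        # both standardise the same contrast, so the psi_hat-scale tail is shared
        pw = p_saddlepoint(dyspepsia_counts, theta06, StatisticKind.WALD).value
        pr = p_saddlepoint(dyspepsia_counts, theta06, StatisticKind.SCORE).value
        assert pw == pytest.approx(pr, abs=1e-12)

    def test_continuity_through_the_mean(self, theta06):
        cg = CGF(theta06, (10, 10, 10), RateTriple(0.38, 0.5, 0.2))
        p_limit, _ = _lr_tail(cg, 0.0)
        p_lo, _ = _lr_tail(cg, -1e-6)
        p_hi, _ = _lr_tail(cg, 1e-6)
        assert p_lo == pytest.approx(p_limit, abs=1e-3)
        assert p_hi == pytest.approx(p_limit, abs=1e-3)

    def test_agrees_with_normal_limit_at_large_n(self, theta06):
        c = TrialCounts(160, 500, 170, 500, 100, 500)
        for kind in StatisticKind:
            pa = p_asymptotic(c, theta06, kind).value
            ps = p_saddlepoint(c, theta06, kind).value
            assert abs(pa - ps) <= 0.01

    def test_small_sample_enumeration_oracle(self, theta06):
        n = 10
        rates = RateTriple(0.6 * 0.5 + 0.4 * 0.2, 0.5, 0.2)
        cg = CGF(theta06, (n, n, n), rates)
        k = np.arange(n + 1)
        xT, xR, xP = np.meshgrid(k, k, k, indexing="ij")
        psi_hat = xT / n - 0.6 * xR / n - 0.4 * xP / n
        w = (
            stats.binom.pmf(k, n, rates.pi_T)[:, None, None]
            * stats.binom.pmf(k, n, rates.pi_R)[None, :, None]
            * stats.binom.pmf(k, n, rates.pi_P)[None, None, :]
        )
        errs = []
        for s in np.arange(-0.3, 0.45, 0.05):
            exact = w[psi_hat >= s - 1e-12].sum()
            approx, _ = _lr_tail(cg, s)
            errs.append(abs(exact - approx))
        assert np.mean(errs) <= 0.02


class TestTailProbability:
    def test_extreme_thresholds(self, theta06):
        rates = RateTriple(0.5, 0.4, 0.3)
        assert tail_probability(StatisticKind.WALD, theta06, (5, 5, 5), rates, -np.inf) == 1.0
        # ties are closed, so a +inf threshold keeps exactly the outcomes whose
        # statistic is itself +inf (degenerate-variance outcomes)
        inf_mass = sum(
            stats.binom.pmf(xT, 5, 0.5) * stats.binom.pmf(xR, 5, 0.4) * stats.binom.pmf(xP, 5, 0.3)
            for xT in range(6)
            for xR in range(6)
            for xP in range(6)
            if statistic(TrialCounts(xT, 5, xR, 5, xP, 5), theta06, StatisticKind.WALD).value
            == np.inf
        )
        got = tail_probability(StatisticKind.WALD, theta06, (5, 5, 5), rates, np.inf)
        assert got == pytest.approx(inf_mass, abs=1e-12)
        assert got < 1e-3

    def test_matches_literal_triple_loop(self, theta06):
        rates = RateTriple(0.5, 0.4, 0.3)
        t0 = statistic(TrialCounts(4, 5, 2, 5, 1, 5), theta06, StatisticKind.WALD).value
        total = 0.0
        for xT in range(6):
            for xR in range(6):
                for xP in range(6):
                    c = TrialCounts(xT, 5, xR, 5, xP, 5)
                    if statistic(c, theta06, StatisticKind.WALD).value >= t0 - 1e-9:
                        total += (
                            stats.binom.pmf(xT, 5, 0.5)
                            * stats.binom.pmf(xR, 5, 0.4)
                            * stats.binom.pmf(xP, 5, 0.3)
                        )
        got = tail_probability(StatisticKind.WALD, theta06, (5, 5, 5), rates, t0)
        assert got == pytest.approx(total, abs=1e-12)

    def test_non_increasing_in_threshold(self, theta06):
        rates = RateTriple(0.5, 0.4, 0.3)
        grid = np.linspace(-3, 3, 13)
        tails = [
            tail_probability(StatisticKind.SCORE, theta06, (5, 5, 5), rates, t0)
            for t0 in grid
        ]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_lattice_cap(self, theta06):
        with pytest.raises(LatticeTooLarge):
            tail_probability(
                StatisticKind.WALD, theta06, (500, 500, 500), RateTriple(0.5, 0.5, 0.5),
                0.0, cap=10_000,
            )


class TestExactUnconditional:
    def test_dominates_plugin_point(self, theta06):
        rng = np.random.default_rng(21)
        for _ in range(8):
            c = random_counts(rng, n_max=6)
            for kind in (StatisticKind.WALD, StatisticKind.SCORE):
                pe = p_exact_unconditional(c, theta06, kind, n_grid=51).value
                pa = p_approx_unconditional(c, theta06, kind).value
                assert pe >= pa - 1e-3

    def test_fine_grid_agrees_with_default(self, theta06):
        c = TrialCounts(3, 4, 2, 4, 0, 4)
        coarse = p_exact_unconditional(c, theta06, StatisticKind.SCORE).value
        fine = p_exact_unconditional(
            c, theta06, StatisticKind.SCORE, n_grid=501, refine=False
        ).value
        assert coarse == pytest.approx(fine, abs=5e-3)

    def test_argmax_recorded_inside_null(self, dyspepsia_counts, theta06):
        pv = p_exact_unconditional(dyspepsia_counts, theta06, StatisticKind.SCORE)
        arg = pv.meta["argmax"]
        assert arg["psi"] <= 1e-12
        assert -1e-12 <= arg["pi_P"] <= arg["pi_R"] <= 1 + 1e-12


class TestApproxUnconditional:
    def test_toy_input_matches_triple_loop_at_null_rmle(self, theta06):
        c = TrialCounts(4, 5, 2, 5, 1, 5)
        tilde = rmle(c, theta06, force_null=True)
        t0 = statistic(c, theta06, StatisticKind.WALD).value
        total = 0.0
        for xT in range(6):
            for xR in range(6):
                for xP in range(6):
                    cc = TrialCounts(xT, 5, xR, 5, xP, 5)
                    if statistic(cc, theta06, StatisticKind.WALD).value >= t0 - 1e-9:
                        total += (
                            stats.binom.pmf(xT, 5, tilde.pi_T)
                            * stats.binom.pmf(xR, 5, tilde.pi_R)
                            * stats.binom.pmf(xP, 5, tilde.pi_P)
                        )
        got = p_approx_unconditional(c, theta06, StatisticKind.WALD).value
        assert got == pytest.approx(total, abs=1e-9)


class TestBootstrap:
    def test_fixed_seed_is_bit_identical(self, dyspepsia_counts, theta06):
        cfg = BootstrapConfig(B=2000, seed=11)
        p1 = p_bootstrap(dyspepsia_counts, theta06, StatisticKind.SCORE, cfg)
        p2 = p_bootstrap(dyspepsia_counts, theta06, StatisticKind.SCORE, cfg)
        assert p1.value == p2.value

    def test_minimal_statistic_gives_one(self, theta06):
        c = TrialCounts(0, 5, 5, 5, 5, 5)  # psi_hat = -1, statistic -inf
        pv = p_bootstrap(c, theta06, StatisticKind.WALD, BootstrapConfig(B=500, seed=1))
        assert pv.value == 1.0

    def test_estimates_unconditional_tail(self, theta06):
        c = TrialCounts(4, 5, 3, 5, 1, 5)
        pa = p_approx_unconditional(c, theta06, StatisticKind.SCORE).value
        pb = p_bootstrap(c, theta06, StatisticKind.SCORE, BootstrapConfig(50_000, 5)).value
        assert pb == pytest.approx(pa, abs=0.01)


class TestUnitInterval:
    def test_every_engine_stays_in_bounds(self, theta06):
        rng = np.random.default_rng(31)
        for _ in range(5):
            c = random_counts(rng, n_max=6)
            for kind in StatisticKind:
                values = [
                    p_asymptotic(c, theta06, kind).value,
                    p_saddlepoint(c, theta06, kind).value,
                    p_exact_unconditional(c, theta06, kind, n_grid=26, refine=False).value,
                    p_approx_unconditional(c, theta06, kind).value,
                    p_bootstrap(c, theta06, kind, BootstrapConfig(200, 2)).value,
                ]
                assert all(0.0 <= v <= 1.0 for v in values), (c, kind, values)
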