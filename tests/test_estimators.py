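"""The five MR estimators, OR conversions and their oracles."""

import numpy as np
import pytest

from helpers import direct_harmonized, sim_harmonized
from mrscreen.estimators import (
    all_estimates,
    ivw,
    mode_estimate,
    mr_egger,
    odds_ratio,
    wald_p_from_or_ci,
    wald_ratio,
    weighted_median,
)
from mrscreen.harmonize import HarmonizedSet


def hset(bx, by, sx=0.01, sy=1.0):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = len(bx)
    return HarmonizedSet(
        np.array([f"s{i}" for i in range(k)], dtype=object),
        bx, np.full(k, sx), by,
        np.full(k, sy) if np.isscalar(sy) else np.asarray(sy, dtype=float),
    )


class TestWaldRatio:
    def test_simple_ratio(self):
        assert wald_ratio(1.0, 0.1, 0.5, 0.1).beta == pytest.approx(0.5)

    def test_negative_denominator(self):
        est = wald_ratio(-0.1, 0.01, 0.2, 0.05)
        assert est.beta == pytest.approx(-2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_bx_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.5, 0.1)

    def test_noise_free_snp_recovers_causal_beta(self):
        H, truth = sim_harmonized(seed=21, k=5, causal_beta=0.37,
                                  n_exp=10**12, n_out=10**12)
        est = wald_ratio(H.bx[0], H.sx[0], H.by[0], H.sy[0])
        assert est.beta == pytest.approx(0.37, abs=1e-3)


class TestIVW:
    def test_identical_ratios_consensus(self):
        H = hset([1.0, 2.0, 0.5], [0.7, 1.4, 0.35])
        est = ivw(H)
        assert est.beta == pytest.approx(0.7)
        assert est.extra["q"] == pytest.approx(0.0, abs=1e-20)

    def test_symmetric_toy_set(self):
        est = ivw(hset([1.0, 1.0, 1.0], [0.9, 1.0, 1.1]))
        assert est.beta == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        """IVW slope equals the bx²/sy²-weighted mean of Wald ratios."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 15))
            H = hset(rng.normal(0.2, 0.1, k) + 0.05, rng.normal(0, 0.2, k),
                     sy=rng.uniform(0.05, 0.5, k))
            w = H.bx**2 / H.sy**2
            oracle = np.sum(w * (H.by / H.bx)) / np.sum(w)
            assert ivw(H).beta == pytest.approx(oracle, rel=1e-10)

    def test_k1_reduces_to_wald_ratio(self):
        H = hset([0.2], [0.1], sy=0.05)
        est = ivw(H)
        wald = wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_fe_vs_mre_inflation(self):
        H = hset([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0])
        fe, mre = ivw(H, mode="fe"), ivw(H, mode="mre")
        assert fe.beta == mre.beta
        q = mre.extra["q"]
        assert mre.se == pytest.approx(fe.se * max(1, np.sqrt(q / 3)))

    def test_empty_rejected(self):
        with pytest.raises((ValueError, Exception)):
            ivw(hset([], []))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 2.0 * bx
        est = mr_egger(hset(bx, by))
        assert est.beta == pytest.approx(2.0, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.05, abs=1e-10)

    def test_minimum_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(hset([0.1, 0.2], [0.1, 0.2]))

    def test_orientation_convention(self):
        """Flipping a SNP's alleles does not change the Egger fit."""
        bx = np.array([0.1, -0.2, 0.3, 0.15])
        by = np.array([0.05, -0.1, 0.2, 0.1])
        est1 = mr_egger(hset(bx, by))
        est2 = mr_egger(hset(-bx, -by))
        assert est1.beta == pytest.approx(est2.beta)
        assert est1.extra["intercept"] == pytest.approx(est2.extra["intercept"])

    def test_directional_pleiotropy_recovered(self):
        """Mean intercept over reps ≈ the planted mean direct effect."""
        intercepts = [
            mr_egger(direct_harmonized(
                seed=1000 + rep, k=30, causal_beta=0.1,
                alpha=np.random.default_rng(70_000 + rep).normal(
                    0.05, 0.01, 30),
            )).extra["intercept"]
            for rep in range(200)
        ]
        intercepts = np.array(intercepts)
        mcse = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean() - 0.05) < 2 * mcse + 1e-4


class TestWeightedMedian:
    def test_equal_weights_plain_median(self, toy_harmonized):
        est = weighted_median(toy_harmonized, n_boot=50, seed=0)
        assert est.beta == pytest.approx(3.0)

    def test_equal_weights_even_k(self):
        H = hset([1.0] * 4, [1.0, 2.0, 3.0, 4.0])
        est = weighted_median(H, n_boot=50, seed=0)
        assert est.beta == pytest.approx(np.median([1, 2, 3, 4]))

    def test_interpolation_oracle(self):
        """Matches direct evaluation of the cumulative-weight formula."""
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 10.0])
        sy = np.array([1.0, 1.0, 2.0])  # weights 1, 1, 0.25
        H = hset(bx, by, sy=sy)
        w = np.array([1.0, 1.0, 0.25])
        s = (np.cumsum(w) - w / 2) / w.sum()  # ratios already sorted
        expected = np.interp(0.5, s, [1.0, 2.0, 10.0])
        est = weighted_median(H, n_boot=50, seed=0)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_reproducible(self, toy_harmonized):
        a = weighted_median(toy_harmonized, n_boot=100, seed=42)
        b = weighted_median(toy_harmonized, n_boot=100, seed=42)
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_minimum_three(self):
        with pytest.raises(ValueError):
            weighted_median(hset([1.0, 1.0], [1.0, 1.0]))


class TestMode:
    def test_degenerate_identical_ratios(self):
        H = hset([1.0] * 4, [0.8] * 4)
        est = mode_estimate(H, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.8)

    def test_majority_cluster_wins(self):
        """Mode sits in the 5-ratio cluster, checked against a fine scan."""
        bx = np.ones(7)
        by = np.array([0.95, 1.0, 1.0, 1.05, 1.0, 5.0, 5.0])
        H = hset(bx, by)
        est = mode_estimate(H, weighted=False, n_boot=50, seed=0)
        assert abs(est.beta - 1.0) < 0.2
        # brute-force density scan oracle on a denser grid
        r = by / bx
        sd = np.std(r, ddof=1)
        mad = np.median(np.abs(r - np.median(r))) / 0.6745
        h = 0.9 * min(sd, mad) * 7 ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 4096)
        dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(1)
        assert abs(est.beta - grid[np.argmax(dens)]) < 0.01

    def test_consistency_with_majority_valid(self):
        """Mean weighted-mode estimate ≈ causal_beta when >50% valid."""
        est = []
        for rep in range(150):
            rng = np.random.default_rng(93_000 + rep)
            alpha = np.zeros(20)
            alpha[:8] = rng.normal(0.08, 0.02, 8)  # 40% invalid
            H = direct_harmonized(seed=3000 + rep, k=20, causal_beta=0.2,
                                  alpha=alpha)
            est.append(mode_estimate(H, weighted=True, n_boot=8,
                                     seed=rep).beta)
        assert abs(np.mean(est) - 0.2) < 0.05

    def test_bootstrap_reproducible(self, toy_harmonized):
        a = mode_estimate(toy_harmonized, n_boot=100, seed=7)
        b = mode_estimate(toy_harmonized, n_boot=100, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestORConversions:
    def test_null_beta_gives_unit_or(self):
        res = odds_ratio(0.0, 0.1)
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_published_protective_association(self):
        res = odds_ratio(-0.1244, 0.03982)
        assert res.or_point == pytest.approx(0.883, abs=5e-4)
        assert res.ci_low == pytest.approx(0.817, abs=1e-3)
        assert res.ci_high == pytest.approx(0.955, abs=1e-3)

    def test_p_reconstruction_round_trip(self):
        est = ivw(hset([0.2, 0.25, 0.3], [0.05, 0.08, 0.06], sy=0.02))
        orr = est.odds_ratio()
        p = wald_p_from_or_ci(orr.or_point, orr.ci_low, orr.ci_high)
        assert p == pytest.approx(est.pvalue, rel=1e-6)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            wald_p_from_or_ci(1.0, 1.1, 1.2)


class TestPanelProperties:
    def test_sign_equivariance(self):
        """Recoding every SNP's alleles leaves all five estimates unchanged."""
        H, _ = sim_harmonized(seed=33, k=12, causal_beta=0.3)
        flipped = HarmonizedSet(H.snp_ids, -H.bx, H.sx, -H.by, H.sy)
        a = all_estimates(H, n_boot=50, seed=5)
        b = all_estimates(flipped, n_boot=50, seed=5)
        for method in a:
            assert a[method].beta == pytest.approx(b[method].beta, rel=1e-8), method

    def test_all_methods_near_truth_strong_signal(self):
        H, _ = sim_harmonized(seed=34, k=30, causal_beta=0.4)
        for method, est in all_estimates(H, n_boot=100, seed=1).items():
            assert est.beta == pytest.approx(0.4, abs=0.1), method
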