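"""Instrument selection: R²/F formulas, p/MAF filtering, greedy clumping."""

import numpy as np
import pandas as pd
import pytest

from mrscreen.instruments import (
    clump,
    f_statistic,
    filter_by_f,
    instrument_stats,
    r2_of_snp,
    select_instruments,
)
from mrscreen.simulate import SimConfig, simulate_two_sample


def snp_frame(rows):
    """rows: (snp_id, chrom, pos, pvalue) — other fields filled in."""
    return pd.DataFrame(
        [
            {
                "snp_id": s, "chrom": str(c), "pos": p, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
                "pvalue": pv, "n": 18340,
            }
            for s, c, p, pv in rows
        ]
    )


def ld_frame(ids, r):
    mat = np.full((len(ids), len(ids)), r, dtype=float)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=ids, columns=ids)


class TestStrengthFormulas:
    def test_zero_beta_gives_zero_r2_and_f(self):
        assert r2_of_snp(0.3, 0.0, 0.02, 10_000) == 0.0
        assert f_statistic(0.0, 10_000, 1) == 0.0

    def test_r2_worked_example(self):
        # beta²/(beta² + n·se²) = 0.01/(0.01 + 4.0)
        r2 = r2_of_snp(0.5, 0.1, 0.02, 10_000)
        assert r2 == pytest.approx(0.01 / 4.01, rel=1e-12)
        assert r2 == pytest.approx(0.0024938, rel=1e-4)

    def test_r2_invariant_to_eaf(self):
        # the 2·EAF(1−EAF) factor cancels
        assert r2_of_snp(0.1, 0.07, 0.013, 20_000) == pytest.approx(
            r2_of_snp(0.4, 0.07, 0.013, 20_000), rel=1e-12
        )

    def test_f_worked_example(self):
        f = f_statistic(0.01 / 4.01, 10_000, 1)
        assert f == pytest.approx(25.0, rel=1e-2)
        # for small r2, F ≈ (beta/se)²·(1 − 2/n) ≈ (beta/se)²
        assert f == pytest.approx((0.1 / 0.02) ** 2, rel=5e-3)

    def test_f_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(0.5, 2, 1)  # n <= k+1
        with pytest.raises(ValueError):
            f_statistic(1.0, 100, 1)
        with pytest.raises(ValueError):
            r2_of_snp(0.0, 0.1, 0.01, 100)


class TestSelect:
    def test_threshold_is_strict(self):
        frame = snp_frame([("a", 1, 100, 1e-5), ("b", 1, 200, 0.99e-5)])
        kept = select_instruments(frame, p_threshold=1e-5)
        assert kept["snp_id"].tolist() == ["b"]

    def test_maf_filter_uses_minor_allele(self):
        frame = snp_frame([("a", 1, 100, 1e-8), ("b", 1, 200, 1e-8)])
        frame.loc[0, "eaf"] = 0.995  # MAF 0.005
        frame.loc[1, "eaf"] = 0.99  # MAF 0.01, boundary kept
        kept = select_instruments(frame, maf_min=0.01)
        assert kept["snp_id"].tolist() == ["b"]

    def test_idempotent(self):
        cfg = SimConfig(m_snps=300, m_instruments=40, gamma_sd=0.15, seed=4)
        exposure, _, _ = simulate_two_sample(cfg)
        once = select_instruments(exposure)
        twice = select_instruments(once)
        assert once.equals(twice)

    def test_matches_brute_force_filter(self):
        cfg = SimConfig(m_snps=1000, m_instruments=50, gamma_sd=0.3, seed=8)
        exposure, _, truth = simulate_two_sample(cfg)
        kept = set(select_instruments(exposure)["snp_id"])
        brute = {
            r.snp_id
            for r in exposure.itertuples()
            if r.pvalue < 1e-5 and min(r.eaf, 1 - r.eaf) >= 0.01
        }
        assert kept == brute
        # with gamma_sd large most true instruments are recovered
        true_ids = set(truth.snp_ids[truth.is_instrument])
        assert len(kept & true_ids) >= 0.8 * len(true_ids)

    def test_f_filter_keeps_only_strong(self):
        frame = snp_frame([("a", 1, 100, 1e-8), ("b", 1, 200, 1e-8)])
        frame.loc[1, "beta"] = 0.001  # F << 10
        strong = filter_by_f(frame, f_min=10)
        assert strong["snp_id"].tolist() == ["a"]
        stats = instrument_stats(strong)
        assert (stats["f_stat"] > 10).all()


def brute_force_clump(frame, lookup_r2, r2_max, window_bp):
    """Independent naive greedy re-implementation used as oracle."""
    rows = sorted(frame.to_dict("records"),
                  key=lambda r: (r["pvalue"], str(r["snp_id"])))
    kept, removed = [], set()
    for row in rows:
        if row["snp_id"] in removed:
            continue
        kept.append(row["snp_id"])
        for other in rows:
            if other["snp_id"] in removed or other["snp_id"] in kept:
                continue
            same_chrom = str(other["chrom"]) == str(row["chrom"])
            close = abs(other["pos"] - row["pos"]) <= window_bp
            if same_chrom and close and lookup_r2(
                str(other["snp_id"]), str(row["snp_id"])
            ) > r2_max:
                removed.add(other["snp_id"])
    return kept


class TestClump:
    def test_correlated_pair_in_window_keeps_best_p(self):
        frame = snp_frame([("a", 1, 1_000_000, 1e-8),
                           ("b", 1, 6_000_000, 1e-6)])
        kept = clump(frame, ld_frame(["a", "b"], 0.95))
        assert kept["snp_id"].tolist() == ["a"]

    def test_correlated_pair_outside_window_both_kept(self):
        frame = snp_frame([("a", 1, 1_000_000, 1e-8),
                           ("b", 1, 21_000_000, 1e-6)])
        kept = clump(frame, ld_frame(["a", "b"], 0.95))
        assert set(kept["snp_id"]) == {"a", "b"}

    def test_different_chromosomes_both_kept(self):
        frame = snp_frame([("a", 1, 1_000_000, 1e-8),
                           ("b", 2, 1_000_000, 1e-6)])
        kept = clump(frame, ld_frame(["a", "b"], 0.95))
        assert set(kept["snp_id"]) == {"a", "b"}

    def test_one_survivor_per_tight_block(self):
        cfg = SimConfig(m_snps=30, m_instruments=30, gamma_sd=0.3,
                        ld_block_size=10, ld_rho=0.95, seed=6)
        exposure, _, truth = simulate_two_sample(cfg)
        kept = clump(exposure, truth.ld_frame(), r2_max=0.001)
        assert len(kept) == 3  # one per block

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        ids = [f"s{i}" for i in range(n)]
        frame = snp_frame(
            [(ids[i], rng.integers(1, 3), int(rng.integers(1, 3)) * 4_000_000
              + i * 1000, float(rng.uniform(1e-9, 1e-5))) for i in range(n)]
        )
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        ld = pd.DataFrame(r, index=ids, columns=ids)
        kept = clump(frame, ld, r2_max=0.3, window_kb=10_000)
        lookup = lambda a, b: float(ld.loc[a, b]) ** 2
        oracle = brute_force_clump(frame, lookup, 0.3, 10_000_000)
        assert kept["snp_id"].tolist() == oracle

    def test_order_invariance(self):
        frame = snp_frame(
            [("a", 1, 1_000_000, 1e-8), ("b", 1, 2_000_000, 1e-6),
             ("c", 1, 3_000_000, 1e-7), ("d", 2, 1_000_000, 1e-6)]
        )
        ld = ld_frame(["a", "b", "c", "d"], 0.5)
        kept = clump(frame, ld)["snp_id"].tolist()
        shuffled = frame.sample(frac=1, random_state=1).reset_index(drop=True)
        assert clump(shuffled, ld)["snp_id"].tolist() == kept

    def test_no_retained_pair_violates_r2(self):
        cfg = SimConfig(m_snps=40, m_instruments=40, gamma_sd=0.3,
                        ld_block_size=5, ld_rho=0.7, seed=9)
        exposure, _, truth = simulate_two_sample(cfg)
        ld = truth.ld_frame()
        kept = clump(exposure, ld, r2_max=0.001)
        ids = kept["snp_id"].tolist()
        pos = dict(zip(kept["snp_id"], kept["pos"]))
        chrom = dict(zip(kept["snp_id"], kept["chrom"]))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= 1e7:
                    assert float(ld.loc[a, b]) ** 2 <= 0.001

    def test_missing_positions_error(self):
        frame = snp_frame([("a", 1, 100, 1e-8)])
        frame.loc[0, "pos"] = np.nan
        with pytest.raises(ValueError):
            clump(frame, None)

    def test_missing_ld_pairs_treated_as_independent(self):
        frame = snp_frame([("a", 1, 1_000_000, 1e-8),
                           ("b", 1, 1_100_000, 1e-6)])
        kept = clump(frame, None)
        assert set(kept["snp_id"]) == {"a", "b"}
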