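"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from mrscreen.harmonize import HarmonizedSet, harmonize_pair
from mrscreen.simulate import SimConfig, simulate_two_sample


def sim_harmonized(seed: int, k: int = 30, **config_kwargs):
    """Generator-backed harmonized set of exactly-k instruments.

    Every SNP is an instrument and no palindromes are drawn, so the
    harmonized set keeps all k SNPs.
    """
    cfg = SimConfig(
        m_snps=k,
        m_instruments=k,
        gamma_sd=config_kwargs.pop("gamma_sd", 0.15),
        palindromic_frac=0.0,
        seed=seed,
        **config_kwargs,
    )
    exposure, outcome, truth = simulate_two_sample(cfg)
    H, _ = harmonize_pair(exposure, outcome)
    return H, truth


def direct_harmonized(
    seed: int,
    k: int = 30,
    causal_beta: float = 0.0,
    alpha=None,
    sx: float = 0.011,
    sy: float = 0.005,
    gamma_low: float = 0.02,
    gamma_sd: float = 0.15,
) -> HarmonizedSet:
    """Hand-built harmonized set with positively oriented true effects.

    Useful for pleiotropy-recovery scenarios where the planted direct
    effect must keep its sign under the Egger bx ≥ 0 orientation.
    ``alpha`` is a length-k vector of per-SNP direct outcome effects.
    """
    rng = np.random.default_rng(seed)
    gamma = np.abs(rng.normal(0.0, gamma_sd, k)) + gamma_low
    alpha = np.zeros(k) if alpha is None else np.asarray(alpha, dtype=float)
    bx = gamma + rng.normal(0.0, sx, k)
    by = causal_beta * gamma + alpha + rng.normal(0.0, sy, k)
    return HarmonizedSet(
        np.array([f"s{i}" for i in range(k)], dtype=object),
        bx,
        np.full(k, sx),
        by,
        np.full(k, sy),
    )
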