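"""Heterogeneity and pleiotropy diagnostics.

* **Cochran's Q** — heterogeneity of the per-SNP Wald ratios around the
  IVW estimate, Q = Σ wⱼ(rⱼ − β)² with wⱼ = bxⱼ²/syⱼ², referred to
  χ²(k−1).  This Wald-ratio parameterization is identical to the
  weighted residual sum of squares of the through-origin regression.
* **MR-Egger intercept test** — the intercept of the Egger fit with a
  t(k−2) reference; a nonzero intercept indicates directional
  pleiotropy.
* **MR-PRESSO** — a simulation-based residual test.  The observed
  statistic is the weighted leave-one-out residual sum of squares
  RSS_obs = Σⱼ wⱼ(byⱼ − β₍₋ⱼ₎bxⱼ)², wⱼ = 1/syⱼ², where β₍₋ⱼ₎ is the
  IVW slope with SNP j removed.  Its null distribution is built by
  parametric simulation (bx*ⱼ ~ N(bxⱼ, sxⱼ), by*ⱼ ~ N(β₍₋ⱼ₎bxⱼ, syⱼ))
  with RSS recomputed identically; the global p is the Monte-Carlo
  exceedance probability.  The outlier test compares each SNP's observed
  squared residual with its simulated distribution, Bonferroni-adjusted
  across SNPs.
* **Leave-one-out** — the IVW fit is repeated excluding each SNP in
  turn; the analysis is flagged when any single exclusion flips the
  sign of the estimate or moves it across nominal significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger
from .harmonize import HarmonizedSet

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso_global",
    "mr_presso_outlier",
    "leave_one_out",
    "sensitivity_report",
]


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_rss_obs: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    loo_estimates: list[MREstimate] = field(default_factory=list)
    loo_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.q_stat < 0.0:
            raise ValueError("q_stat must be >= 0")
        if self.presso_global_p is not None and not 0.0 < self.presso_global_p <= 1.0:
            raise ValueError("presso_global_p must be in (0, 1]")


def cochran_q(
    H: HarmonizedSet, beta_ivw: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom k−1, and the χ² p-value."""
    if H.k < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    w = H.bx**2 / H.sy**2
    r = H.wald_ratios()
    if beta_ivw is None:
        beta_ivw = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_ivw) ** 2))
    df = H.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(H: HarmonizedSet) -> tuple[float, float, float]:
    """Intercept, SE and t(k−2) p-value of the MR-Egger fit."""
    fit = mr_egger(H)
    return (
        fit.extra["intercept"],
        fit.extra["intercept_se"],
        fit.extra["intercept_p"],
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each SNP removed; vectorized over leading axes."""
    s_xy = (w * bx * by).sum(axis=-1, keepdims=True)
    s_xx = (w * bx**2).sum(axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _presso_residuals2(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray
) -> np.ndarray:
    b_loo = _loo_slopes(bx, by, w)
    return w * (by - b_loo * bx) ** 2


def _presso(
    H: HarmonizedSet, n_sim: int, seed, add_one: bool
) -> tuple[float, float, np.ndarray, np.ndarray]:
    if H.k < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    w = 1.0 / H.sy**2
    e2_obs = _presso_residuals2(H.bx, H.by, w)
    rss_obs = float(e2_obs.sum())
    b_loo_obs = _loo_slopes(H.bx, H.by, w)

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(H.bx, H.sx, size=(n_sim, H.k))
    by_sim = rng.normal(b_loo_obs * H.bx, H.sy, size=(n_sim, H.k))
    e2_sim = _presso_residuals2(bx_sim, by_sim, w)
    rss_sim = e2_sim.sum(axis=1)

    extra = 1 if add_one else 0
    global_p = (int(np.sum(rss_sim >= rss_obs)) + extra) / (n_sim + extra)
    global_p = min(max(global_p, np.finfo(float).tiny), 1.0)
    return rss_obs, float(global_p), e2_obs, e2_sim


def mr_presso_global(
    H: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    add_one: bool = True,
) -> tuple[float, float]:
    """MR-PRESSO global test: (RSS_obs, Monte-Carlo p).

    ``add_one`` applies the (r+1)/(n+1) correction so the p-value is a
    valid Monte-Carlo p and never exactly zero; the raw fraction is
    available with ``add_one=False``.
    """
    rss_obs, p, _, _ = _presso(H, n_sim, seed, add_one)
    return rss_obs, p


def mr_presso_outlier(
    H: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    add_one: bool = True,
    alpha: float = 0.05,
) -> list[tuple[str, float]]:
    """Per-SNP outlier p-values, Bonferroni-adjusted across the k SNPs.

    Returns ``(snp_id, adjusted_p)`` for every SNP; callers flag those
    with adjusted p below ``alpha`` and re-estimate after exclusion.
    Uses the same simulation stream as the global test when given the
    same seed.
    """
    _, _, e2_obs, e2_sim = _presso(H, n_sim, seed, add_one)
    extra = 1 if add_one else 0
    raw = (np.sum(e2_sim >= e2_obs[None, :], axis=0) + extra) / (n_sim + extra)
    adj = np.minimum(raw * H.k, 1.0)
    return [(str(s), float(p)) for s, p in zip(H.snp_ids, adj)]


def leave_one_out(
    H: HarmonizedSet, ivw_mode: str = "mre", alpha: float = 0.05
) -> tuple[list[MREstimate], bool]:
    """IVW re-fit excluding each SNP in turn.

    The flag is True when any single exclusion flips the sign of the
    estimate or moves the IVW p-value across ``alpha`` in either
    direction relative to the full fit.
    """
    if H.k < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    full = ivw(H, mode=ivw_mode)
    estimates: list[MREstimate] = []
    flag = False
    for j in range(H.k):
        mask = np.ones(H.k, dtype=bool)
        mask[j] = False
        fit = ivw(H.subset(mask), mode=ivw_mode)
        fit.extra["excluded_snp"] = str(H.snp_ids[j])
        estimates.append(fit)
        if np.sign(fit.beta) != np.sign(full.beta):
            flag = True
        if (fit.pvalue < alpha) != (full.pvalue < alpha):
            flag = True
    return estimates, flag


def sensitivity_report(
    H: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    ivw_mode: str = "mre",
) -> SensitivityReport:
    """Run every diagnostic applicable at the pair's instrument count."""
    q, df, qp = cochran_q(H)
    report = SensitivityReport(q_stat=q, q_df=df, q_pvalue=qp)
    if H.k >= 3:
        ei, ei_se, ei_p = egger_intercept_test(H)
        report.egger_intercept = ei
        report.egger_intercept_se = ei_se
        report.egger_intercept_p = ei_p
        loo, flag = leave_one_out(H, ivw_mode=ivw_mode)
        report.loo_estimates = loo
        report.loo_flag = flag
    if H.k >= 4:
        rss, gp = mr_presso_global(H, n_sim=n_sim, seed=seed)
        report.presso_rss_obs = rss
        report.presso_global_p = gp
        outliers = mr_presso_outlier(H, n_sim=n_sim, seed=seed)
        report.presso_outliers = [s for s, p in outliers if p < 0.05]
    return report
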