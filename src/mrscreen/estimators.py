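"""Causal-effect estimators for two-sample summary-data MR.

Five estimators are provided, each consuming a :class:`HarmonizedSet` of
per-SNP exposure effects bx (SE sx) and outcome effects by (SE sy):

* **Wald ratio** — the single-SNP estimate by/bx with first-order
  delta-method SE sy/|bx|.
* **IVW** — the inverse-variance-weighted combination of Wald ratios,
  equivalently a weighted regression of by on bx through the origin
  with weights 1/sy².  The default is multiplicative random effects:
  the fixed-effect SE is inflated by max(1, sqrt(Q/(k−1))) where Q is
  Cochran's heterogeneity statistic; under-dispersion is truncated at 1.
* **MR-Egger** — weighted least squares of by on bx with a free
  intercept; the slope estimates the causal effect even under
  directional pleiotropy and the intercept measures its average size.
  SNPs are oriented so bx ≥ 0 before fitting; inference uses a t
  reference with k−2 degrees of freedom.
* **Weighted median** — the weighted median of Wald ratios with weights
  bx²/sy² (inverse Wald-ratio variance); consistent when at least half
  of the weight comes from valid instruments.  SE by parametric
  bootstrap.
* **Mode (simple / weighted)** — the mode of the smoothed Wald-ratio
  density; consistent when the largest cluster of instruments is valid.
  Bandwidth follows the modified Silverman rule
  h = phi · 0.9 · min(SD, MAD/0.6745) · k^(−1/5).  SE by parametric
  bootstrap.

Binary-outcome effects are log odds ratios, so exp(beta) with
exp(beta ± 1.96·se) gives the OR and 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate",
    "ORResult",
    "METHODS",
    "wald_ratio",
    "ivw",
    "cochran_q_statistic",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "all_estimates",
    "odds_ratio",
    "wald_p_from_or_ci",
]

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

Z_95 = 1.96  # conventional 95% normal quantile, matching printed-CI practice


@dataclass
class MREstimate:
    """One method's causal estimate on the beta (log-OR / SD) scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0.0:
            raise ValueError("se must be > 0")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue must be in (0, 1]")

    def odds_ratio(self) -> "ORResult":
        return odds_ratio(self.beta, self.se)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with its 95% confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_low < self.or_point < self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with delta-method SE sy/|bx|."""
    if bx == 0.0:
        raise ValueError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald", beta, se, _norm_p(beta / se), n_snp=1)


def cochran_q_statistic(H: HarmonizedSet, beta: float | None = None) -> float:
    """Cochran's Q of the Wald ratios around ``beta`` (IVW slope if None)."""
    w = H.bx**2 / H.sy**2
    r = H.wald_ratios()
    if beta is None:
        beta = float(np.sum(w * r) / np.sum(w))
    return float(np.sum(w * (r - beta) ** 2))


def ivw(H: HarmonizedSet, mode: Literal["mre", "fe"] = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode="mre"`` (default) applies multiplicative random effects:
    SE inflated by max(1, sqrt(Q/(k−1))).  ``mode="fe"`` keeps the
    fixed-effect SE.  With a single SNP the estimate reduces to the
    Wald ratio (fixed-effect SE; no heterogeneity is estimable).
    """
    k = H.k
    if k < 1:
        raise ValueError("ivw needs at least one SNP")
    w = 1.0 / H.sy**2
    s_xx = float(np.sum(w * H.bx**2))
    beta = float(np.sum(w * H.bx * H.by)) / s_xx
    se = 1.0 / np.sqrt(s_xx)
    q = cochran_q_statistic(H, beta)
    if mode == "mre" and k >= 2:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    elif mode not in ("mre", "fe"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    return MREstimate(
        "ivw", beta, float(se), _norm_p(beta / se), n_snp=k,
        extra={"q": q, "q_df": max(k - 1, 0), "mode": mode},
    )


def _orient(H: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    sign = np.where(H.bx < 0.0, -1.0, 1.0)
    return H.bx * sign, H.by * sign


def mr_egger(H: HarmonizedSet) -> MREstimate:
    """MR-Egger regression slope; the intercept sits in ``extra``.

    extra keys: ``intercept``, ``intercept_se``, ``intercept_p``,
    ``residual_sd`` (the weighted residual SD, truncated at 1 for SE
    scaling).
    """
    if H.k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx, by = _orient(H)
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / H.sy**2).fit()
    df = H.k - 2
    sigma = float(np.sqrt(fit.scale))  # weighted residual SD
    scale_factor = max(1.0, sigma)
    # statsmodels bse already carry sigma; rescale to max(1, sigma)
    se = np.asarray(fit.bse) / sigma * scale_factor
    params = np.asarray(fit.params)
    slope, slope_se = float(params[1]), float(se[1])
    inter, inter_se = float(params[0]), float(se[0])
    p_slope = float(np.clip(2.0 * stats.t.sf(abs(slope / slope_se), df), 1e-300, 1.0))
    p_inter = float(np.clip(2.0 * stats.t.sf(abs(inter / inter_se), df), 1e-300, 1.0))
    return MREstimate(
        "egger", slope, slope_se, p_slope, n_snp=H.k,
        extra={
            "intercept": inter,
            "intercept_se": inter_se,
            "intercept_p": p_inter,
            "residual_sd": sigma,
        },
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="mergesort")
    r_sorted, w_sorted = r[order], w[order]
    s = (np.cumsum(w_sorted) - 0.5 * w_sorted) / np.sum(w_sorted)
    return float(np.interp(0.5, s, r_sorted))


def _parametric_boot(
    H: HarmonizedSet, point_fn, n_boot: int, seed
) -> float:
    rng = np.random.default_rng(seed)
    bx = rng.normal(H.bx, H.sx, size=(n_boot, H.k))
    by = rng.normal(H.by, H.sy, size=(n_boot, H.k))
    est = np.array([point_fn(bx[i], by[i]) for i in range(n_boot)])
    sd = float(np.std(est, ddof=1))
    return max(sd, 1e-300)


def weighted_median(
    H: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    if H.k < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    r = H.wald_ratios()
    w = H.bx**2 / H.sy**2
    beta = _weighted_median_point(r, w)

    def point(bx, by):
        return _weighted_median_point(by / bx, bx**2 / H.sy**2)

    se = _parametric_boot(H, point, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta / se), n_snp=H.k)


def _mode_point(
    r: np.ndarray, w: np.ndarray, phi: float, n_grid: int = 512
) -> float:
    k = len(r)
    sd = float(np.std(r, ddof=1))
    mad = float(stats.median_abs_deviation(r, scale=1.0)) / 0.6745
    h = phi * 0.9 * min(sd, mad) * k ** (-0.2)
    if h <= 0.0 or not np.isfinite(h):
        # all ratios (or half of them) identical: density degenerates
        return float(np.median(r))
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(
        axis=1
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    H: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator (weighted or simple) with bootstrap SE."""
    if H.k < 3:
        raise ValueError("mode estimator needs at least 3 SNPs")
    r = H.wald_ratios()
    if np.ptp(r) == 0.0:
        beta = float(r[0])
    else:
        w = H.bx**2 / H.sy**2 if weighted else np.ones(H.k)
        beta = _mode_point(r, w, phi)

    def point(bx, by):
        rb = by / bx
        if np.ptp(rb) == 0.0:
            return float(rb[0])
        wb = bx**2 / H.sy**2 if weighted else np.ones(H.k)
        return _mode_point(rb, wb, phi)

    se = _parametric_boot(H, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, _norm_p(beta / se), n_snp=H.k)


def all_estimates(
    H: HarmonizedSet,
    ivw_mode: Literal["mre", "fe"] = "mre",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, MREstimate]:
    """The five-method panel used by the screen (requires k ≥ 3)."""
    ss = np.random.SeedSequence(seed)
    s_med, s_simple, s_weighted = [
        int(c.generate_state(1, dtype=np.uint32)[0]) for c in ss.spawn(3)
    ]
    return {
        "ivw": ivw(H, mode=ivw_mode),
        "egger": mr_egger(H),
        "weighted_median": weighted_median(H, n_boot=n_boot, seed=s_med),
        "simple_mode": mode_estimate(
            H, weighted=False, phi=phi, n_boot=n_boot, seed=s_simple
        ),
        "weighted_mode": mode_estimate(
            H, weighted=True, phi=phi, n_boot=n_boot, seed=s_weighted
        ),
    }


def odds_ratio(beta: float, se: float) -> ORResult:
    """exp-transform a log-OR and its 95% CI."""
    if not se > 0.0:
        raise ValueError("se must be > 0")
    return ORResult(
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
    )


def wald_p_from_or_ci(or_point: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p reconstructed from an OR and its 95% CI.

    The SE is recovered from the CI width on the log scale,
    se = (ln ci_high − ln ci_low)/(2·1.96), and the p-value is the
    two-sided normal tail of ln(OR)/se.  Used to check published
    OR/CI/p triples for internal consistency.
    """
    if not 0.0 < ci_low < or_point < ci_high:
        raise ValueError("require 0 < ci_low < or < ci_high")
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * 1.96)
    if se == 0.0:
        return 1.0
    return _norm_p(np.log(or_point) / se)
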