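"""Screen orchestration, significance logic and result tables.

For every exposure-outcome pair the pipeline runs: association +
MAF selection → LD clumping → weak-instrument (F > 10) filter →
allele harmonization → the five-estimator panel → sensitivity
diagnostics.  A pair is *nominal* when the IVW p-value is below 0.05
and all five estimators agree in sign; it is *Bonferroni-significant*
when additionally the IVW p-value falls below the per-taxonomic-level
threshold 0.05/n, where n is the number of taxa tested at that level.
The default level counts are those of the 211-taxon microbiota GWAS
battery (9 phyla, 16 classes, 20 orders, 35 families, 131 genera);
synthetic batteries supply their own counts.

The reverse screen re-runs the identical machinery with the outcome
acting as exposure, restricted to taxa that were nominal forward hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import METHODS, MREstimate, all_estimates, odds_ratio
from .harmonize import HarmonizationError, harmonize_pair
from .instruments import clump, filter_by_f, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .simulate import Battery, BatteryPair
from .sumstats import StudyMeta

__all__ = [
    "DEFAULT_LEVEL_COUNTS",
    "ScreenConfig",
    "TaxonResult",
    "direction_consistent",
    "bonferroni_threshold",
    "analyze_pair",
    "run_screen",
    "run_reverse",
    "results_table",
    "sensitivity_table",
    "export_forest",
]

DEFAULT_LEVEL_COUNTS: dict[str, int] = {
    "phylum": 9,
    "class": 16,
    "order": 20,
    "family": 35,
    "genus": 131,
}


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds, estimator options and seeds for one screen run."""

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    maf_min: float = 0.01
    f_min: float = 10.0
    drop_palindromic: bool = True
    ivw_mode: str = "mre"
    phi: float = 1.0
    n_boot: int = 1000
    n_sim: int = 1000
    alpha: float = 0.05
    seed: int = 0
    level_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_COUNTS)
    )
    exclude_taxa: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclude_taxa" in raw:
            raw["exclude_taxa"] = tuple(raw["exclude_taxa"])
        return cls(**raw)


@dataclass
class TaxonResult:
    """Everything the screen learned about one exposure-outcome pair."""

    taxon_level: str
    taxon_id: str
    taxon_name: str
    outcome: str
    status: str = "ok"  # ok | failed
    reason: str = ""
    stage_counts: dict = field(default_factory=dict)
    estimates: dict[str, MREstimate] | None = None
    sensitivity: SensitivityReport | None = None
    nominal: bool = False
    bonferroni_sig: bool = False
    level_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.bonferroni_sig and not self.nominal:
            raise ValueError("bonferroni_sig requires nominal")
        if not 0.0 < self.level_threshold <= 0.05:
            raise ValueError("level_threshold must be in (0, 0.05]")


def direction_consistent(estimates: Mapping[str, MREstimate]) -> bool:
    """True iff all five methods estimate the same nonzero sign."""
    missing = [m for m in METHODS if m not in estimates]
    if missing:
        raise ValueError(f"missing methods: {missing}")
    signs = {np.sign(estimates[m].beta) for m in METHODS}
    return len(signs) == 1 and 0.0 not in signs


def bonferroni_threshold(
    level: str, level_counts: Mapping[str, int] | None = None
) -> float:
    """Per-level multiple-testing threshold 0.05/n."""
    counts = DEFAULT_LEVEL_COUNTS if level_counts is None else level_counts
    if level not in counts:
        raise ValueError(f"unknown taxonomic level {level!r}")
    n = counts[level]
    if n < 1:
        raise ValueError("level count must be >= 1")
    return 0.05 / n


def _pair_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def analyze_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | None,
    meta: StudyMeta,
    outcome_name: str,
    config: ScreenConfig,
    seed: int | None = None,
) -> TaxonResult:
    """Run the full per-pair pipeline and apply the significance logic."""
    level = meta.taxon_level if meta.taxon_level != "none" else "genus"
    threshold = bonferroni_threshold(level, config.level_counts)
    result = TaxonResult(
        taxon_level=meta.taxon_level,
        taxon_id=meta.taxon_id,
        taxon_name=meta.trait_name,
        outcome=outcome_name,
        level_threshold=threshold,
    )
    seed = config.seed if seed is None else seed

    selected = select_instruments(
        exposure, p_threshold=config.p_threshold, maf_min=config.maf_min
    )
    counts = {"input": len(exposure), "selected": len(selected)}
    if selected.empty:
        result.status, result.reason = "failed", "no_instruments"
        result.stage_counts = counts
        return result
    clumped = clump(
        selected, ld, r2_max=config.clump_r2, window_kb=config.clump_kb
    )
    counts["clumped"] = len(clumped)
    strong = filter_by_f(clumped, f_min=config.f_min)
    counts["f_filtered"] = len(strong)
    if strong.empty:
        result.status, result.reason = "failed", "no_strong_instruments"
        result.stage_counts = counts
        return result
    try:
        H, exclusions = harmonize_pair(
            strong, outcome, drop_palindromic=config.drop_palindromic
        )
    except HarmonizationError as exc:
        result.status, result.reason = "failed", str(exc)
        result.stage_counts = counts
        return result
    counts["harmonized"] = H.k
    result.stage_counts = counts
    result.exclusions = exclusions  # type: ignore[attr-defined]
    if H.k < 3:
        result.status = "failed"
        result.reason = f"too_few_snps_after_harmonization ({H.k} < 3)"
        return result

    estimates = all_estimates(
        H, ivw_mode=config.ivw_mode, phi=config.phi,
        n_boot=config.n_boot, seed=seed,
    )
    result.estimates = estimates
    result.sensitivity = sensitivity_report(
        H, n_sim=config.n_sim, seed=seed, ivw_mode=config.ivw_mode
    )
    ivw_p = estimates["ivw"].pvalue
    result.nominal = ivw_p < config.alpha and direction_consistent(estimates)
    result.bonferroni_sig = result.nominal and ivw_p < threshold
    return result


def run_screen(battery: Battery, config: ScreenConfig) -> list[TaxonResult]:
    """Forward screen: every battery taxon against the shared outcome."""
    results: list[TaxonResult] = []
    cfg = replace(config, level_counts=dict(battery.level_counts))
    for i, pair in enumerate(battery.pairs):
        if pair.meta.trait_name in config.exclude_taxa:
            continue
        results.append(
            analyze_pair(
                pair.exposure,
                battery.outcome,
                pair.ld,
                pair.meta,
                battery.outcome_meta.trait_name,
                cfg,
                seed=_pair_seed(config.seed, i),
            )
        )
    return results


def run_reverse(
    battery: Battery,
    forward_results: Sequence[TaxonResult],
    config: ScreenConfig,
    outcome_ld: pd.DataFrame | None = None,
) -> list[TaxonResult]:
    """Reverse screen restricted to taxa that were nominal forward hits.

    The shared outcome study acts as the exposure; each nominal taxon's
    study is the outcome.  ``outcome_ld`` carries the LD structure of
    the outcome study's SNPs (block-diagonal concatenation of the
    per-taxon truths in synthetic batteries).
    """
    nominal_names = {r.taxon_name for r in forward_results if r.nominal}
    if outcome_ld is None:
        # per-taxon LD blocks are independent: treat them block-diagonally
        outcome_ld = [p.ld for p in battery.pairs]
    results: list[TaxonResult] = []
    for i, pair in enumerate(battery.pairs):
        if pair.meta.trait_name not in nominal_names:
            continue
        meta = StudyMeta(
            trait_name=battery.outcome_meta.trait_name,
            trait_role="exposure",
            trait_type=battery.outcome_meta.trait_type,
            taxon_level=pair.meta.taxon_level,
            taxon_id=pair.meta.taxon_id,
        )
        res = analyze_pair(
            battery.outcome,
            pair.exposure,
            outcome_ld,
            meta,
            pair.meta.trait_name,
            replace(config, level_counts=dict(battery.level_counts)),
            seed=_pair_seed(config.seed + 1, i),
        )
        res.taxon_name = f"{battery.outcome_meta.trait_name}->{pair.meta.trait_name}"
        results.append(res)
    return results


def results_table(results: Iterable[TaxonResult]) -> pd.DataFrame:
    """Tidy per-method table: one row per (pair, method)."""
    rows = []
    for res in results:
        base = {
            "taxon_level": res.taxon_level,
            "taxon_id": res.taxon_id,
            "exposure": res.taxon_name,
            "outcome": res.outcome,
            "status": res.status,
            "reason": res.reason,
            "nominal": res.nominal,
            "bonferroni_sig": res.bonferroni_sig,
            "level_threshold": res.level_threshold,
        }
        if res.estimates is None:
            rows.append(base | {"method": "", "n_snp": res.stage_counts.get(
                "harmonized", 0)})
            continue
        for method, est in res.estimates.items():
            orr = est.odds_ratio()
            rows.append(
                base
                | {
                    "method": method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "pvalue": est.pvalue,
                    "or": orr.or_point,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(results: Iterable[TaxonResult]) -> pd.DataFrame:
    """Diagnostics table: Egger intercept, MR-PRESSO RSS/p, Cochran's Q p."""
    rows = []
    for res in results:
        s = res.sensitivity
        if s is None:
            continue
        rows.append(
            {
                "exposure": res.taxon_name,
                "outcome": res.outcome,
                "egger_intercept": s.egger_intercept,
                "egger_intercept_se": s.egger_intercept_se,
                "egger_intercept_p": s.egger_intercept_p,
                "presso_rss_obs": s.presso_rss_obs,
                "presso_global_p": s.presso_global_p,
                "presso_n_outliers": len(s.presso_outliers),
                "q_stat": s.q_stat,
                "q_pvalue": s.q_pvalue,
                "loo_flag": s.loo_flag,
            }
        )
    return pd.DataFrame(rows)


_LEVEL_ORDER = {"phylum": 0, "class": 1, "order": 2, "family": 3, "genus": 4,
                "none": 5}


def export_forest(
    results: Sequence[TaxonResult],
    path: str | Path,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the IVW forest table (and optionally a rendered forest plot).

    One row per analyzable pair: exposure, outcome, n_snp, OR, 95% CI
    and p-value, ordered by taxonomic level then p-value.
    """
    if not results:
        raise ValueError("no results to export")
    rows = []
    for res in results:
        if res.estimates is None:
            continue
        est = res.estimates["ivw"]
        orr = est.odds_ratio()
        rows.append(
            {
                "taxon_level": res.taxon_level,
                "exposure": res.taxon_name,
                "outcome": res.outcome,
                "n_snp": est.n_snp,
                "or": orr.or_point,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "pvalue": est.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["taxon_level", "pvalue"],
            key=lambda s: s.map(_LEVEL_ORDER) if s.name == "taxon_level" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    table.to_csv(path, sep="\t", index=False)
    if plot_path is not None and not table.empty:
        _render_forest(table, plot_path)
    return table


def _render_forest(table: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.arange(len(table))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    ax.errorbar(
        table["or"], y,
        xerr=[table["or"] - table["ci_low"], table["ci_high"] - table["or"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="red", linestyle="--", linewidth=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(
        [f"{r.exposure} → {r.outcome}" for r in table.itertuples()]
    )
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
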