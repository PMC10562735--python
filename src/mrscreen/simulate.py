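"""Synthetic paired GWAS summary statistics with known ground truth.

The generator works at the summary-statistic level (no individual
genotypes): for each SNP j it draws an effect-allele frequency, derives
the theoretical standard error of an additive GWAS beta,
``se = 1/sqrt(2·EAF·(1−EAF)·N)``, and samples observed effects around
the true instrument effect γⱼ (exposure) and ``β·γⱼ + αⱼ`` (outcome),
where β is the causal effect and αⱼ a direct (pleiotropic) effect.  A
nonzero mean of αⱼ produces directional pleiotropy (a nonzero MR-Egger
intercept); ``het_sd`` adds unmodelled outcome variance (Cochran's Q
heterogeneity).  Exposure sampling noise is correlated within LD blocks,
and the block correlation matrix is returned alongside the records so
clumping can be exercised without a reference panel.

Defaults mirror the study design being emulated: a microbiota-abundance
exposure GWAS of 18,340 participants whose taxa typically contribute a
handful of sub-genome-wide (p < 1e-5) instruments each, paired with a
large binary outcome study on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import Study, StudyMeta, frame_to_records, write_sumstats

__all__ = [
    "SimConfig",
    "TruthRecord",
    "BatteryPair",
    "Battery",
    "simulate_two_sample",
    "simulate_battery",
    "write_ld",
    "read_ld",
    "write_truth",
]

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)

# blocks on one chromosome are spaced 20 Mb apart, twice the default
# clumping window, so distinct blocks are never clumped together
_BLOCK_SPACING_BP = 20_000_000
_WITHIN_BLOCK_SPACING_BP = 5_000
_N_CHROMS = 22


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one paired exposure/outcome simulation.

    ``causal_beta`` is the true causal effect of the exposure on the
    outcome (log-OR per SD of exposure for a binary outcome);
    ``gamma_sd`` scales true instrument effects; ``pleio_mean`` /
    ``pleio_sd`` parameterize per-SNP direct effects on the outcome;
    ``het_sd`` adds extra outcome noise beyond the theoretical SE.
    """

    m_snps: int = 500
    m_instruments: int = 12
    n_exp: int = 18_340
    n_out: int = 100_000
    causal_beta: float = 0.0
    gamma_sd: float = 0.08
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    het_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.0
    palindromic_frac: float = 0.2
    outcome_swap_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.m_snps <= 0:
            raise ValueError("m_snps must be positive")
        if not 0 <= self.m_instruments <= self.m_snps:
            raise ValueError("m_instruments must be in [0, m_snps]")
        low, high = self.maf_range
        if not 0.0 < low < high < 1.0:
            raise ValueError("maf_range must satisfy 0 < low < high < 1")
        if not abs(self.ld_rho) < 1.0:
            raise ValueError("|ld_rho| must be < 1")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ValueError("palindromic_frac must be in [0, 1]")
        if min(self.n_exp, self.n_out) <= 2:
            raise ValueError("sample sizes must exceed 2")
        for name in ("gamma_sd", "pleio_sd", "het_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated pair."""

    causal_beta: float
    snp_ids: np.ndarray  # (m,) str
    gamma: np.ndarray  # (m,) true exposure effects
    alpha: np.ndarray  # (m,) direct outcome effects
    is_instrument: np.ndarray  # (m,) bool
    block_index: np.ndarray  # (m,) int
    ld_rho: float

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        for name in ("gamma", "alpha", "is_instrument", "block_index"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"truth field {name} has wrong length")

    def ld_frame(self) -> pd.DataFrame:
        """Block-diagonal signed-correlation matrix as a labelled DataFrame."""
        m = len(self.snp_ids)
        mat = np.eye(m)
        for b in np.unique(self.block_index):
            idx = np.flatnonzero(self.block_index == b)
            mat[np.ix_(idx, idx)] = self.ld_rho
            mat[idx, idx] = 1.0
        ids = [str(s) for s in self.snp_ids]
        return pd.DataFrame(mat, index=ids, columns=ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "is_instrument": self.is_instrument.astype(int),
            }
        )


def _theoretical_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _equicorrelated_noise(
    rng: np.random.Generator, block_index: np.ndarray, rho: float
) -> np.ndarray:
    """Standard-normal draws with pairwise correlation rho within blocks.

    Uses the one-factor representation z = sqrt(rho)·u_block +
    sqrt(1−rho)·e (valid for rho ≥ 0); negative rho falls back to a
    Cholesky factor per block.
    """
    m = len(block_index)
    if rho == 0.0:
        return rng.standard_normal(m)
    if rho > 0.0:
        u = rng.standard_normal(block_index.max() + 1)
        e = rng.standard_normal(m)
        return np.sqrt(rho) * u[block_index] + np.sqrt(1.0 - rho) * e
    out = np.empty(m)
    for b in np.unique(block_index):
        idx = np.flatnonzero(block_index == b)
        k = len(idx)
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        out[idx] = np.linalg.cholesky(corr) @ rng.standard_normal(k)
    return out


def _assign_positions(block_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.empty(len(block_index), dtype=object)
    pos = np.empty(len(block_index), dtype=np.int64)
    within = np.zeros(len(block_index), dtype=np.int64)
    counts: dict[int, int] = {}
    for i, b in enumerate(block_index):
        within[i] = counts.get(b, 0)
        counts[b] = within[i] + 1
    chrom_of_block = (block_index % _N_CHROMS) + 1
    block_rank_on_chrom = block_index // _N_CHROMS
    chroms[:] = chrom_of_block.astype(str)
    pos[:] = (
        1
        + block_rank_on_chrom * _BLOCK_SPACING_BP
        + within * _WITHIN_BLOCK_SPACING_BP
    )
    return chroms, pos


def simulate_two_sample(
    config: SimConfig, snp_prefix: str = "rs"
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate one exposure study, one outcome study and their truth.

    Returns two canonical-column summary-statistic DataFrames and a
    :class:`TruthRecord`.  Output is a pure function of ``config``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_snps

    snp_ids = np.array([f"{snp_prefix}{j + 1}" for j in range(m)], dtype=object)
    block_index = np.arange(m) // config.ld_block_size
    chroms, pos = _assign_positions(block_index)

    eaf = rng.uniform(*config.maf_range, size=m)
    se_exp = _theoretical_se(eaf, config.n_exp)
    se_out = _theoretical_se(eaf, config.n_out)

    is_instrument = np.zeros(m, dtype=bool)
    is_instrument[: config.m_instruments] = True
    gamma = np.where(
        is_instrument, rng.normal(0.0, config.gamma_sd, size=m), 0.0
    )
    alpha = rng.normal(config.pleio_mean, config.pleio_sd, size=m)

    noise_exp = _equicorrelated_noise(rng, block_index, config.ld_rho) * se_exp
    beta_exp = gamma + noise_exp
    out_noise_sd = np.sqrt(se_out**2 + config.het_sd**2)
    beta_out = config.causal_beta * gamma + alpha + rng.normal(0.0, out_noise_sd)

    palindromic = rng.random(m) < config.palindromic_frac
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        pair = (
            _PALINDROMIC_PAIRS[pal_choice[j]]
            if palindromic[j]
            else _NONPALINDROMIC_PAIRS[non_choice[j]]
        )
        ea[j], oa[j] = pair

    exposure = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_exp,
            "se": se_exp,
            "pvalue": _two_sided_p(beta_exp, se_exp),
            "n": config.n_exp,
        }
    )

    # optional re-encoding of the outcome rows onto the other allele, to
    # exercise harmonization: same association, opposite orientation
    swap = rng.random(m) < config.outcome_swap_frac
    out_ea = np.where(swap, oa, ea)
    out_oa = np.where(swap, ea, oa)
    out_eaf = np.where(swap, 1.0 - eaf, eaf)
    out_beta = np.where(swap, -beta_out, beta_out)
    outcome = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": out_ea,
            "other_allele": out_oa,
            "eaf": out_eaf,
            "beta": out_beta,
            "se": se_out,
            "pvalue": _two_sided_p(out_beta, se_out),
            "n": config.n_out,
        }
    )

    truth = TruthRecord(
        causal_beta=config.causal_beta,
        snp_ids=snp_ids,
        gamma=gamma,
        alpha=alpha,
        is_instrument=is_instrument,
        block_index=block_index,
        ld_rho=config.ld_rho,
    )
    return exposure, outcome, truth


@dataclass
class BatteryPair:
    """One taxon's exposure study with its LD matrix and truth."""

    meta: StudyMeta
    exposure: pd.DataFrame
    ld: pd.DataFrame
    truth: TruthRecord


@dataclass
class Battery:
    """A multi-taxon exposure battery sharing one outcome study."""

    pairs: list[BatteryPair]
    outcome: pd.DataFrame
    outcome_meta: StudyMeta
    manifest: pd.DataFrame
    level_counts: dict[str, int]


def _derive_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_battery(
    levels: Mapping[str, int],
    template: SimConfig,
    causal_taxa: Mapping[str, float] | None = None,
    outcome_name: str = "outcome",
    outcome_type: str = "binary",
    out_dir: str | Path | None = None,
) -> Battery:
    """Simulate one exposure study per taxon plus a shared outcome study.

    ``levels`` maps taxonomic level → number of taxa at that level (the
    Bonferroni denominators of the battery).  Taxon seeds are derived
    deterministically from ``template.seed``; ``causal_taxa`` overrides
    ``causal_beta`` for named taxa (all others use the template's value).
    When ``out_dir`` is given, sumstats/LD/truth TSVs and a manifest are
    written there.
    """
    causal_taxa = dict(causal_taxa or {})
    for level, count in levels.items():
        if level not in ("phylum", "class", "order", "family", "genus"):
            raise ValueError(f"unknown taxonomic level {level!r}")
        if count < 0:
            raise ValueError("taxon counts must be >= 0")

    pairs: list[BatteryPair] = []
    outcome_frames: list[pd.DataFrame] = []
    rows: list[dict] = []
    index = 0
    for level in sorted(levels):
        for i in range(levels[level]):
            taxon = f"{level}.t{i + 1:03d}"
            cfg = replace(
                template,
                seed=_derive_seed(template.seed, index),
                causal_beta=causal_taxa.get(taxon, template.causal_beta),
            )
            exp, out, truth = simulate_two_sample(
                cfg, snp_prefix=f"rs{index + 1}_"
            )
            meta = StudyMeta(
                trait_name=taxon,
                trait_role="exposure",
                trait_type="continuous",
                taxon_level=level,
                taxon_id=f"id.{1000 + index}",
            )
            pairs.append(BatteryPair(meta, exp, truth.ld_frame(), truth))
            outcome_frames.append(out)
            rows.append(
                {
                    "taxon_level": level,
                    "taxon_id": meta.taxon_id,
                    "trait_name": taxon,
                    "n_snps": len(exp),
                    "causal_beta": cfg.causal_beta,
                    "seed": cfg.seed,
                }
            )
            index += 1

    outcome = (
        pd.concat(outcome_frames, ignore_index=True)
        if outcome_frames
        else pd.DataFrame()
    )
    outcome_meta = StudyMeta(
        trait_name=outcome_name, trait_role="outcome", trait_type=outcome_type
    )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "taxon_level", "taxon_id", "trait_name", "n_snps", "causal_beta", "seed",
        ],
    )
    battery = Battery(
        pairs=pairs,
        outcome=outcome,
        outcome_meta=outcome_meta,
        manifest=manifest,
        level_counts={lv: n for lv, n in levels.items() if n > 0},
    )
    if out_dir is not None:
        _write_battery(battery, Path(out_dir))
    return battery


def _write_battery(battery: Battery, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = battery.manifest.copy()
    sumstats_paths, ld_paths, truth_paths = [], [], []
    for pair in battery.pairs:
        stem = pair.meta.trait_name
        sp, lp, tp = (
            out_dir / f"{stem}.tsv",
            out_dir / f"{stem}.ld.tsv",
            out_dir / f"{stem}.truth.tsv",
        )
        write_sumstats(frame_to_records(pair.exposure), sp, meta=pair.meta)
        write_ld(pair.ld, lp)
        write_truth(pair.truth, tp)
        sumstats_paths.append(sp.name)
        ld_paths.append(lp.name)
        truth_paths.append(tp.name)
    manifest["sumstats"] = sumstats_paths
    manifest["ld"] = ld_paths
    manifest["truth"] = truth_paths
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    write_sumstats(
        frame_to_records(battery.outcome),
        out_dir / "outcome.tsv",
        meta=battery.outcome_meta,
    )


def write_ld(ld: pd.DataFrame, path: str | Path) -> None:
    """Write a square signed-correlation matrix as TSV with SNP-id labels."""
    ld.to_csv(path, sep="\t", index=True, index_label="snp_id")


def read_ld(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snp_id")


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    truth.frame().to_csv(path, sep="\t", index=False)


def study_from_frame(frame: pd.DataFrame, meta: StudyMeta) -> Study:
    """Convenience wrapper validating a simulated frame into a Study."""
    return Study(frame_to_records(frame), meta)
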