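"""Instrument selection: association threshold, MAF filter, LD clumping,
and instrument-strength statistics (per-SNP variance explained and F).

The variance a SNP explains in the exposure is computed from summary
statistics as

    R² = 2·EAF·(1−EAF)·Beta² / (2·EAF·(1−EAF)·Beta² + 2·EAF·(1−EAF)·N·SE²)

which algebraically reduces to Beta² / (Beta² + N·SE²) — the 2·EAF(1−EAF)
factor cancels.  The F-statistic for K instruments explaining a combined
R² in a study of N individuals is F = R²(N−K−1) / (K(1−R²)); the
weak-instrument screen enforced by the pipeline is the per-SNP (K=1)
F > 10 convention.

LD is supplied as a signed-correlation matrix (e.g. from the synthetic
generator's known block structure) rather than estimated from a
reference panel; clumping is the standard greedy procedure: repeatedly
keep the most significant remaining SNP and discard SNPs on the same
chromosome within the window whose r² with it exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentStats",
    "r2_of_snp",
    "f_statistic",
    "instrument_stats",
    "select_instruments",
    "filter_by_f",
    "clump",
]


@dataclass(frozen=True)
class InstrumentStats:
    """Strength statistics for one SNP (or one instrument set)."""

    snp_id: str
    r2: float
    f_stat: float
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError(f"r2 {self.r2} outside [0, 1)")
        if self.f_stat < 0.0:
            raise ValueError("f_stat must be >= 0")


def r2_of_snp(eaf: float, beta: float, se: float, n: float) -> float:
    """Proportion of exposure variance explained by one SNP.

    Evaluates the summary-statistic formula above; accepts scalars or
    numpy arrays.
    """
    eaf = np.asarray(eaf, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise ValueError("eaf must be in (0, 1)")
    if np.any(se <= 0.0):
        raise ValueError("se must be > 0")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    v = 2.0 * eaf * (1.0 - eaf)
    num = v * beta**2
    r2 = num / (num + v * n * se**2)
    return float(r2) if r2.ndim == 0 else r2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """F-statistic for k instruments jointly explaining r2 in n samples."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0.0) | (r2 >= 1.0)):
        raise ValueError("r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any(n <= k + 1):
        raise ValueError("n must exceed k + 1")
    f = r2 * (n - k - 1) / (k * (1.0 - r2))
    return float(f) if f.ndim == 0 else f


def instrument_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP R² and F (K=1) plus the joint F over the whole set.

    Returns a copy of ``records`` with ``r2`` and ``f_stat`` columns and
    attaches the set-level statistics as ``DataFrame.attrs['joint']``.
    """
    out = records.copy()
    r2 = r2_of_snp(out["eaf"].to_numpy(), out["beta"].to_numpy(),
                   out["se"].to_numpy(), out["n"].to_numpy())
    out["r2"] = r2
    out["f_stat"] = f_statistic(r2, out["n"].to_numpy(), k=1)
    k = len(out)
    if k >= 1:
        joint_r2 = float(np.sum(r2))
        n_min = float(out["n"].min())
        joint = InstrumentStats(
            snp_id="<set>",
            r2=min(joint_r2, np.nextafter(1.0, 0.0)),
            f_stat=f_statistic(min(joint_r2, np.nextafter(1.0, 0.0)), n_min, k=k)
            if n_min > k + 1
            else 0.0,
            k=k,
        )
        out.attrs["joint"] = joint
    return out


def select_instruments(
    records: pd.DataFrame,
    p_threshold: float = 1e-5,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Keep SNPs with p-value strictly below the threshold and MAF ≥ maf_min.

    The association threshold is strict (a p-value exactly at the
    threshold is excluded); the minor-allele frequency is
    ``min(EAF, 1−EAF)``.
    """
    maf = np.minimum(records["eaf"], 1.0 - records["eaf"])
    keep = (records["pvalue"] < p_threshold) & (maf >= maf_min)
    return records.loc[keep].reset_index(drop=True)


def filter_by_f(records: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Drop weak instruments: keep SNPs whose per-SNP F exceeds ``f_min``."""
    with_stats = instrument_stats(records)
    keep = with_stats["f_stat"] > f_min
    return records.loc[keep.to_numpy()].reset_index(drop=True)


def _r2_lookup(ld_matrix):
    """Build an (a, b) → r² lookup from None, one matrix, or block matrices.

    A list of square labelled DataFrames is treated as block-diagonal:
    SNP pairs living in different blocks (or absent entirely) have r²=0.
    """
    if ld_matrix is None:
        return lambda a, b: 0.0
    blocks = ld_matrix if isinstance(ld_matrix, (list, tuple)) else [ld_matrix]
    idx: dict[str, tuple[int, int]] = {}
    mats: list[np.ndarray] = []
    for b, frame in enumerate(blocks):
        mats.append(frame.to_numpy(dtype=float))
        for i, s in enumerate(frame.index.astype(str)):
            idx[s] = (b, i)

    def lookup(a: str, b: str) -> float:
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None or ia[0] != ib[0]:
            return 0.0
        return float(mats[ia[0]][ia[1], ib[1]]) ** 2

    return lookup


def clump(
    records: pd.DataFrame,
    ld_matrix,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping; deterministic regardless of input row order.

    Repeatedly retain the remaining SNP with the smallest p-value
    (ties broken by snp_id), then discard remaining SNPs on the same
    chromosome within ``window_kb`` kilobases whose squared correlation
    with it exceeds ``r2_max``.  ``ld_matrix`` is a labelled square
    DataFrame, a list of such blocks (block-diagonal), or None; SNP
    pairs absent from it are treated as uncorrelated.
    """
    if records.empty:
        return records.reset_index(drop=True)
    if records["pos"].isna().any():
        raise ValueError("clump requires positions for every SNP")
    r2 = _r2_lookup(ld_matrix)
    window_bp = window_kb * 1000.0

    order = records.assign(_snp=records["snp_id"].astype(str)).sort_values(
        ["pvalue", "_snp"], kind="mergesort"
    )
    remaining = list(order.index)
    info = {
        i: (str(records.at[i, "snp_id"]), str(records.at[i, "chrom"]),
            float(records.at[i, "pos"]))
        for i in remaining
    }
    kept: list[int] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        lead_id, lead_chrom, lead_pos = info[lead]
        remaining = [
            i
            for i in remaining
            if not (
                info[i][1] == lead_chrom
                and abs(info[i][2] - lead_pos) <= window_bp
                and r2(info[i][0], lead_id) > r2_max
            )
        ]
    return records.loc[kept].reset_index(drop=True)
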