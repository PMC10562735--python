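"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both studies' effects expressed for the same allele
of each SNP.  For each instrument the outcome study is searched for the
same SNP; if its alleles match the exposure orientation the row is kept
as-is, if they are swapped the outcome beta is negated and its EAF
complemented, and if they only match after strand complementation
(A/G recorded as T/C on the other strand) the complemented orientation
is used.  Palindromic SNPs (A/T or C/G) cannot be strand-resolved from
alleles alone and are dropped outright — no frequency-based rescue.
Every input SNP ends up either in the harmonized set or in the exclusion
log with one reason: ``absent_in_outcome``, ``palindromic`` or
``allele_mismatch``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizedSet",
    "HarmonizationError",
    "is_palindromic",
    "complement",
    "harmonize_pair",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EXCLUSION_REASONS = ("absent_in_outcome", "palindromic", "allele_mismatch")


class HarmonizationError(ValueError):
    """The pair cannot be analyzed (no SNP survives harmonization)."""


@dataclass
class HarmonizedSet:
    """Aligned per-SNP effect vectors for one exposure-outcome pair."""

    snp_ids: np.ndarray
    bx: np.ndarray  # exposure effects
    sx: np.ndarray  # exposure SEs
    by: np.ndarray  # outcome effects (exposure effect-allele orientation)
    sy: np.ndarray  # outcome SEs

    def __post_init__(self) -> None:
        arrays = [self.snp_ids, self.bx, self.sx, self.by, self.sy]
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("bx", "sx", "by", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("harmonized vectors must share one length")
        if self.k < 1:
            raise HarmonizationError("empty harmonized set")
        if np.any(self.sx <= 0.0) or np.any(self.sy <= 0.0):
            raise ValueError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        return HarmonizedSet(
            self.snp_ids[mask], self.bx[mask], self.sx[mask],
            self.by[mask], self.sy[mask],
        )

    def wald_ratios(self) -> np.ndarray:
        return self.by / self.bx


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def complement(allele: str) -> str:
    return _COMPLEMENT[allele.upper()]


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromic: bool = True,
    try_strand_flip: bool = True,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Align an instrument-selected exposure frame with an outcome frame.

    Returns the harmonized effect vectors and an exclusion log with one
    ``(snp_id, reason)`` row per dropped SNP.  Harmonization is
    idempotent: feeding back an already-aligned pair changes nothing.

    Raises
    ------
    HarmonizationError
        If no SNP survives, the pair cannot be analyzed.
    """
    out_by_id: dict[str, tuple[str, str, float, float]] = {
        str(r.snp_id): (str(r.effect_allele), str(r.other_allele),
                        float(r.beta), float(r.se))
        for r in outcome.itertuples(index=False)
    }

    ids, bx, sx, by, sy = [], [], [], [], []
    excluded: list[tuple[str, str]] = []
    for r in exposure.itertuples(index=False):
        snp = str(r.snp_id)
        ea, oa = str(r.effect_allele).upper(), str(r.other_allele).upper()
        if drop_palindromic and is_palindromic(ea, oa):
            excluded.append((snp, "palindromic"))
            continue
        hit = out_by_id.get(snp)
        if hit is None:
            excluded.append((snp, "absent_in_outcome"))
            continue
        o_ea, o_oa, o_beta, o_se = hit
        o_ea, o_oa = o_ea.upper(), o_oa.upper()
        candidates = [(o_ea, o_oa, o_beta)]
        if try_strand_flip and not is_palindromic(o_ea, o_oa):
            candidates.append((complement(o_ea), complement(o_oa), o_beta))
        aligned_beta = None
        for c_ea, c_oa, c_beta in candidates:
            if (c_ea, c_oa) == (ea, oa):
                aligned_beta = c_beta
                break
            if (c_ea, c_oa) == (oa, ea):
                aligned_beta = -c_beta
                break
        if aligned_beta is None:
            excluded.append((snp, "allele_mismatch"))
            continue
        ids.append(snp)
        bx.append(float(r.beta))
        sx.append(float(r.se))
        by.append(aligned_beta)
        sy.append(o_se)

    log = pd.DataFrame(excluded, columns=["snp_id", "reason"])
    if not ids:
        raise HarmonizationError(
            "no SNP survives harmonization; pair cannot be analyzed"
        )
    return HarmonizedSet(np.array(ids, dtype=object), bx, sx, by, sy), log
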