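"""Reference results from the published gut-microbiota → thyroid MR screen.

The packaged table carries every inverse-variance-weighted association
the source screen reported (33 forward exposure-outcome pairs across
FT4, TSH, hypothyroidism and hyperthyroidism, plus 2 reverse-direction
pairs), each as an odds ratio with its 95% CI and p-value.  These rows
serve as worked examples: the p-values can be reconstructed from the
OR/CI pairs with :func:`mrscreen.estimators.wald_p_from_or_ci`, and the
per-level Bonferroni thresholds applied to the forward rows reproduce
the published count of associations that survive multiple-testing
correction.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .estimators import wald_p_from_or_ci
from .report import bonferroni_threshold

__all__ = [
    "load_published_screen",
    "reconstructed_pvalues",
    "bonferroni_survivors",
]


def load_published_screen() -> pd.DataFrame:
    """The packaged published-screen table as a DataFrame."""
    ref = resources.files("mrscreen").joinpath("data/published_screen.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reconstructed_pvalues(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add a ``p_reconstructed`` column from each row's OR and 95% CI."""
    if table is None:
        table = load_published_screen()
    table = table.copy()
    table["p_reconstructed"] = [
        wald_p_from_or_ci(o, lo, hi)
        for o, lo, hi in zip(table["or"], table["ci_low"], table["ci_high"])
    ]
    return table


def bonferroni_survivors(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Forward associations whose published IVW p beats 0.05/n for their level."""
    if table is None:
        table = load_published_screen()
    forward = table[table["direction"] == "forward"].copy()
    forward["level_threshold"] = [
        bonferroni_threshold(level) for level in forward["taxon_level"]
    ]
    return forward[forward["pvalue"] < forward["level_threshold"]].reset_index(
        drop=True
    )
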