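"""Kinase-motif enrichment and the relative kinase activity score.

For every kinase and direction (up / down) within a treatment
comparison, a 2x2 table counts how often the kinase appears in the
top-k kinase sets of regulated (foreground) versus all other quantified
(background) phosphosites.  One-sided Fisher exact tests are corrected
per comparison by Benjamini-Hochberg across both directions; the
signed relative kinase activity is the product of the min-max
normalized significance and the log2 frequency factor of each kinase's
most significant direction (positive for up, negative for down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .differential import DOWN, UP, minmax_normalize, significance_weight
from .errors import ValidationError

logger = logging.getLogger(__name__)


def build_contingency(member_sites: set, foreground: set, background: set) -> np.ndarray:
    """[[fg_hits, fg_miss], [bg_hits, bg_miss]] for one kinase.

    ``member_sites`` are the sites whose top-k kinase set contains the
    kinase; ``background`` is all quantified sites of the comparison not
    in the foreground.
    """
    if not foreground:
        raise ValidationError("foreground is empty; enrichment is untestable")
    if not background:
        raise ValidationError("background is empty (foreground covers all sites)")
    if foreground & background:
        raise ValidationError("foreground and background must be disjoint")
    fg_hits = len(member_sites & foreground)
    bg_hits = len(member_sites & background)
    return np.array(
        [[fg_hits, len(foreground) - fg_hits],
         [bg_hits, len(background) - bg_hits]],
        dtype=int,
    )


def fisher_one_sided(table: np.ndarray) -> float:
    """Upper-tail Fisher exact p: P(X >= fg_hits) under the hypergeometric null."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("contingency table must be 2x2 with nonnegative counts")
    a = table[0, 0]
    total = int(table.sum())
    if total == 0:
        return 1.0  # empty table: P(X >= 0) is trivially 1
    hits = int(table[0, 0] + table[1, 0])
    fg = int(table[0, 0] + table[0, 1])
    # P(X >= a) for X ~ Hypergeom(total, hits, fg)
    return float(hypergeom.sf(a - 1, total, hits, fg))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, within [p, 1])."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def frequency_factor(table: np.ndarray) -> float:
    """log2 of (foreground hit rate / background hit rate).

    When any cell is zero, 0.5 is added to all four cells (Haldane-style
    continuity) so the ratio stays finite.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("contingency table must be 2x2 with nonnegative counts")
    if (table == 0).any():
        table = table + 0.5
    fg_rate = table[0, 0] / (table[0, 0] + table[0, 1])
    bg_rate = table[1, 0] / (table[1, 0] + table[1, 1])
    return float(np.log2(fg_rate / bg_rate))


@dataclass
class KinaseActivity:
    """Signed relative activity of one kinase in one comparison."""

    kinase: str
    comparison: str
    activity: float
    direction: str


def kinase_enrichment(
    membership: dict[str, set],
    calls: pd.DataFrame,
    comparison: str,
) -> pd.DataFrame:
    """Per-kinase, per-direction enrichment table for one comparison.

    Parameters
    ----------
    membership : dict
        kinase -> set of site ids whose top-k kinase set contains it.
    calls : pandas.DataFrame
        Output of :func:`kinlink.differential.regulation_scores`
        restricted to one comparison (columns ``site``, ``direction``).
    comparison : str
        Label recorded in the output.

    Directions whose foreground is empty are untestable: they are
    flagged (``testable = False``) and excluded from the BH family.
    """
    rows = []
    all_sites = set(calls["site"])
    for direction in (UP, DOWN):
        foreground = set(calls.loc[calls["direction"] == direction, "site"])
        background = all_sites - foreground
        for kinase in sorted(membership):
            if not foreground or not background:
                rows.append(dict(kinase=kinase, comparison=comparison,
                                 direction=direction, fg_hits=0,
                                 fg_size=len(foreground), bg_hits=0,
                                 bg_size=len(background), frequency_factor=np.nan,
                                 p=np.nan, testable=False))
                continue
            table = build_contingency(membership[kinase], foreground, background)
            rows.append(dict(kinase=kinase, comparison=comparison,
                             direction=direction,
                             fg_hits=int(table[0, 0]), fg_size=len(foreground),
                             bg_hits=int(table[1, 0]), bg_size=len(background),
                             frequency_factor=frequency_factor(table),
                             p=fisher_one_sided(table), testable=True))
    result = pd.DataFrame(rows)
    result["adj_p"] = np.nan
    testable = result["testable"].to_numpy()
    if testable.any():
        result.loc[testable, "adj_p"] = bh_adjust(result.loc[testable, "p"])
    return result


def relative_kinase_activity(
    enrichment: pd.DataFrame,
    p_weight_transform: str = "neglog10",
) -> pd.DataFrame:
    """Signed relative kinase activity for one comparison.

    For each kinase the most significant direction is chosen (smaller
    adjusted p; ties broken by larger |frequency factor|, then up before
    down).  The min-max normalization of -log10(adjusted p) is taken
    over the chosen results of all kinases in the comparison; the
    activity is that weight times the chosen frequency factor, signed
    positive for up and negative for down (the frequency factor's own
    sign is preserved within the direction).  Kinases untestable in both
    directions are omitted with a log entry.
    """
    chosen_rows = []
    for kinase, group in enrichment.groupby("kinase", sort=True):
        testable = group[group["testable"]]
        if testable.empty:
            logger.info("kinase %s untestable in both directions; omitted", kinase)
            continue
        ranked = testable.copy()
        ranked["_dir_rank"] = (ranked["direction"] != UP).astype(int)
        ranked = ranked.sort_values(
            by=["adj_p", "frequency_factor", "_dir_rank"],
            key=lambda col: -col.abs() if col.name == "frequency_factor" else col,
        )
        chosen_rows.append(ranked.iloc[0])
    if not chosen_rows:
        return pd.DataFrame(columns=["kinase", "comparison", "direction",
                                     "frequency_factor", "adj_p", "activity"])
    chosen = pd.DataFrame(chosen_rows).reset_index(drop=True)
    weight = significance_weight(chosen["adj_p"], p_weight_transform)
    sign = np.where(chosen["direction"] == UP, 1.0, -1.0)
    chosen["activity"] = sign * weight * chosen["frequency_factor"].to_numpy()
    return chosen[["kinase", "comparison", "direction", "fg_hits", "fg_size",
                   "bg_hits", "bg_size", "frequency_factor", "p", "adj_p",
                   "activity"]]


__all__ = [
    "build_contingency", "fisher_one_sided", "bh_adjust", "frequency_factor",
    "KinaseActivity", "kinase_enrichment", "relative_kinase_activity",
    "minmax_normalize",
]
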