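"""Differential phosphosite calling and the signed regulation score.

A phosphosite is called regulated in a treatment comparison when its
|log2 fold change| and BH-adjusted p-value pass the configured
thresholds (both inclusive).  The signed relative differential-
regulation score is the product of a min-max-normalized significance
weight and the log2 fold change; it carries the fold change's sign and
feeds the final kinase-substrate interaction score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Columns a phosphosite table must carry.
SITE_COLUMNS = ("site", "protein", "position", "residue", "window",
                "comparison", "log2fc", "adj_p")

UP, DOWN, NS = "up", "down", "ns"


def call_differential(log2fc: float, adj_p: float, config: RunConfig) -> str:
    """Direction call for one site: ``up``, ``down`` or ``ns``.

    Boundary values are inclusive: log2FC = +-log2fc_min with
    adj_p = adjp_max is called.
    """
    if not 0 < adj_p <= 1:
        raise ValidationError(f"adjusted p must be in (0, 1], got {adj_p}")
    if adj_p <= config.adjp_max:
        if log2fc >= config.log2fc_min:
            return UP
        if log2fc <= -config.log2fc_min:
            return DOWN
    return NS


def minmax_normalize(values) -> np.ndarray:
    """Map values to [0, 1] by (v - min) / (max - min).

    A constant input maps to all zeros (documented degenerate rule).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot min-max normalize an empty collection")
    if not np.isfinite(arr).all():
        raise ValidationError("min-max normalization requires finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def significance_weight(adj_p, transform: str = "neglog10") -> np.ndarray:
    """Min-max-normalized significance of adjusted p-values.

    The default transform is -log10(p), so the smallest p in the family
    gets weight 1 and the largest weight 0.  ``raw`` and ``one_minus``
    are offered for sensitivity analyses.  Zero p-values are clamped to
    the smallest positive float before the log, with a warning.
    """
    arr = np.asarray(adj_p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("adjusted p-values must lie in [0, 1]")
    if (arr == 0).any():
        logger.warning("adjusted p of 0 clamped to the smallest positive float")
        arr = np.where(arr == 0, np.nextafter(0.0, 1.0), arr)
    if transform == "neglog10":
        return minmax_normalize(-np.log10(arr))
    if transform == "raw":
        # direct min-max of p; larger p -> larger weight (kept for comparison)
        return minmax_normalize(arr)
    if transform == "one_minus":
        return minmax_normalize(1.0 - arr)
    raise ValidationError(f"unknown p transform {transform!r}")


def regulation_scores(sites: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Direction calls and signed regulation scores, per comparison.

    Normalization of the significance weight is taken across all
    quantified sites of each treatment comparison.  Returns the input
    columns plus ``direction`` and ``score``; ``ns`` sites keep their
    computed score but are excluded from enrichment foregrounds
    downstream.
    """
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise SchemaError(f"phosphosite table is missing columns {sorted(missing)}")
    out = sites.copy()
    out["direction"] = [
        call_differential(fc, p, config)
        for fc, p in zip(out["log2fc"], out["adj_p"])
    ]
    out["score"] = np.nan
    for _, idx in out.groupby("comparison").groups.items():
        weight = significance_weight(out.loc[idx, "adj_p"],
                                     config.p_weight_transform)
        out.loc[idx, "score"] = weight * out.loc[idx, "log2fc"].to_numpy()
    return out
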