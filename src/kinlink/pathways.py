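"""Gene-set overrepresentation analysis and dependency partitioning.

Overrepresentation uses the one-tailed hypergeometric test with BH
correction; gene sets represented by fewer than ``min_background``
members in the background are skipped and excluded from the BH family.
Genes are partitioned into essential / non-essential by a Chronos
dependency cutoff (<= -0.5 is essential, boundary inclusive) and the
ORA is run separately on each partition of the foreground against the
background of all detected phosphoproteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import RunConfig
from .differential import DOWN, UP
from .enrichment import bh_adjust
from .errors import ValidationError

logger = logging.getLogger(__name__)

ESSENTIAL, NON_ESSENTIAL = "essential", "non-essential"


@dataclass
class DependencyCall:
    gene: str
    chronos: float
    label: str


def classify_dependency(gene: str, chronos: float,
                        threshold: float = -0.5) -> DependencyCall:
    """Essential iff the Chronos score is at or below the threshold."""
    if not np.isfinite(chronos):
        raise ValidationError(f"Chronos score for {gene} must be finite")
    label = ESSENTIAL if chronos <= threshold else NON_ESSENTIAL
    return DependencyCall(gene=gene, chronos=float(chronos), label=label)


def hypergeom_ora(
    foreground: set,
    gene_set,
    background: set,
    min_bg: int = 3,
) -> dict | None:
    """One-tailed hypergeometric overrepresentation of one gene set.

    Returns None (skipped) when the set has fewer than ``min_bg``
    members in the background.  The enrichment ratio is the foreground
    proportion over the background proportion.
    """
    foreground, members, background = set(foreground), set(gene_set), set(background)
    if not foreground <= background:
        raise ValidationError("foreground must be a subset of the background")
    if not background:
        raise ValidationError("background is empty")
    bg_hits = len(members & background)
    if bg_hits < min_bg:
        return None
    fg_hits = len(members & foreground)
    n_fg, n_bg = len(foreground), len(background)
    # P(X >= fg_hits), X ~ Hypergeom(N=n_bg, K=bg_hits, n=n_fg)
    p = float(hypergeom.sf(fg_hits - 1, n_bg, bg_hits, n_fg))
    fg_rate = fg_hits / n_fg if n_fg else 0.0
    ratio = fg_rate / (bg_hits / n_bg)
    return dict(fg_hits=fg_hits, fg_size=n_fg, bg_hits=bg_hits, bg_size=n_bg,
                enrichment_ratio=ratio, p=p)


def ora_table(
    foreground: set,
    gene_sets: dict,
    background: set,
    min_bg: int = 3,
) -> pd.DataFrame:
    """ORA over a family of gene sets with BH correction.

    Skipped (sub-minimum-background) sets are absent from the output and
    from the BH family.
    """
    rows = []
    for name in sorted(gene_sets):
        result = hypergeom_ora(foreground, gene_sets[name], background, min_bg)
        if result is None:
            logger.info("gene set %s below minimum background (%d); skipped",
                        name, min_bg)
            continue
        rows.append(dict(gene_set=name, **result))
    table = pd.DataFrame(rows, columns=["gene_set", "fg_hits", "fg_size",
                                        "bg_hits", "bg_size",
                                        "enrichment_ratio", "p"])
    table["adj_p"] = bh_adjust(table["p"]) if len(table) else np.nan
    return table


def co_regulated_proteins(calls: pd.DataFrame) -> set:
    """Proteins with at least one up- and one down-regulated site in a comparison."""
    up = set(calls.loc[calls["direction"] == UP, "protein"])
    down = set(calls.loc[calls["direction"] == DOWN, "protein"])
    return up & down


def select_protein_class(calls: pd.DataFrame, protein_class: str) -> set:
    """Foreground selector over one comparison's calls.

    ``up-only`` / ``down-only`` are proteins whose regulated sites all go
    one way; ``co-regulated`` have sites going both ways; ``any`` is any
    protein with a regulated site.
    """
    up = set(calls.loc[calls["direction"] == UP, "protein"])
    down = set(calls.loc[calls["direction"] == DOWN, "protein"])
    if protein_class == "up-only":
        return up - down
    if protein_class == "down-only":
        return down - up
    if protein_class == "co-regulated":
        return up & down
    if protein_class == "any":
        return up | down
    raise ValidationError(f"unknown protein class {protein_class!r}")


def dependency_partition_ora(
    phosphoproteins: set,
    dependency: pd.DataFrame,
    gene_sets: dict,
    config: RunConfig,
    background: set | None = None,
) -> dict[str, pd.DataFrame]:
    """ORA run separately on essential and non-essential foregrounds.

    The foreground phosphoproteins are partitioned by the Chronos
    cutoff; genes without a dependency score are logged and excluded
    from both partitions.  The background defaults to all genes in the
    dependency-annotated universe union the foreground; pass the set of
    all detected phosphoproteins explicitly for the standard analysis.
    BH runs within each partition family.
    """
    chronos = dict(zip(dependency["gene"], dependency["chronos"]))
    missing = {g for g in phosphoproteins if g not in chronos}
    if missing:
        logger.info("%d foreground genes lack dependency scores; dropped",
                    len(missing))
    scored = set(phosphoproteins) - missing
    essential = {g for g in scored
                 if chronos[g] <= config.chronos_essential_max}
    non_essential = scored - essential
    if background is None:
        background = set(chronos) | scored

    def _family(foreground: set) -> pd.DataFrame:
        if not foreground:
            return pd.DataFrame(columns=["gene_set", "fg_hits", "fg_size",
                                         "bg_hits", "bg_size",
                                         "enrichment_ratio", "p", "adj_p"])
        return ora_table(foreground & background, gene_sets, background,
                         config.min_background)

    return {ESSENTIAL: _family(essential),
            NON_ESSENTIAL: _family(non_essential)}
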