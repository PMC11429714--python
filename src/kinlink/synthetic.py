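"""Synthetic inputs with planted ground truth.

Every table the pipeline consumes can be generated here: a kinase motif
library, a differential phosphosite table, curated evidence and
interaction tables, gene sets, and gene dependency scores.  Known
active kinases, motif-true substrates and essential genes are planted
so every downstream stage can be validated by recovery.

The default scenario plants 2 up-active and 1 down-active kinases among
50, with 2000 phosphosites on 400 proteins, 5% of sites regulated at a
mean |log2FC| of 3 over a null standard deviation of 0.3 -- strong,
acutely-drug-responsive signaling on a phosphoproteome two orders of
magnitude smaller than a real TMT experiment, sized so the whole
pipeline runs in seconds.

Fold changes and p-values are jointly consistent: each site's raw
p-value is the two-sided normal tail of its log2FC over the null
standard deviation, and adjusted p-values come from the pipeline's own
BH step, so null sites carry uniform p-values and planted sites carry
the significance their effect size implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import RunConfig
from .enrichment import bh_adjust
from .errors import ParameterError
from .io import PathwayGeneSet, site_id
from .motifs import (ALPHABET, CENTER_INDEX, KinaseMotifModel, POSITIONS,
                     WINDOW_LENGTH, BASIC_AMPK, BASIC_ROCK, HYDROPHOBIC)

AMPK_LIKE = "AMPK_SYN"
ROCK_LIKE = "ROCK_SYN"

_MOTIF_CLASSES = ("CAMK", "AGC", "CMGC", "STE", "TKL", "Atypical", "Other")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic experiment."""

    active_kinases_up: frozenset = frozenset()
    active_kinases_down: frozenset = frozenset()
    planted_substrates: dict[str, set] = field(default_factory=dict)
    effect_size: float = 3.0
    noise_sd: float = 0.3
    n_sites: int = 2000
    n_proteins: int = 400
    n_kinases: int = 50
    fraction_regulated: float = 0.05
    comparison: str = "combination_vs_control"
    essential_genes: frozenset = frozenset()
    planted_pathways: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.active_kinases_up & self.active_kinases_down:
            raise ParameterError("up- and down-active kinase sets must be disjoint")
        if not 0 <= self.fraction_regulated < 1:
            raise ParameterError(
                f"fraction_regulated must be in [0, 1), got {self.fraction_regulated}"
            )
        if self.noise_sd <= 0 or self.effect_size < 0:
            raise ParameterError("noise_sd must be > 0 and effect_size >= 0")
        for name in ("n_sites", "n_proteins", "n_kinases"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


def default_truth(seed_kinases: list[str] | None = None, n_up: int = 2,
                  n_down: int = 1, **overrides) -> SyntheticTruth:
    """The default scenario: first planted kinases active, AMPK-like first."""
    truth = SyntheticTruth(**overrides)
    names = seed_kinases or kinase_names(truth.n_kinases)
    if n_up + n_down > len(names):
        raise ParameterError("more active kinases requested than exist")
    return replace(truth,
                   active_kinases_up=frozenset(names[:n_up]),
                   active_kinases_down=frozenset(names[n_up:n_up + n_down]))


def kinase_names(n_kinases: int) -> list[str]:
    """Deterministic kinase names; AMPK- and ROCK-like models come first."""
    if n_kinases < 2:
        raise ParameterError(f"need at least 2 kinases, got {n_kinases}")
    names = [AMPK_LIKE, ROCK_LIKE]
    names += [f"KIN{i:03d}" for i in range(n_kinases - 2)]
    return names


# -- kinase library ------------------------------------------------------

def _blank_matrix(rng: np.random.Generator) -> pd.DataFrame:
    noise = rng.normal(0.0, 0.1, size=(WINDOW_LENGTH, len(ALPHABET)))
    matrix = pd.DataFrame(noise, index=list(POSITIONS), columns=list(ALPHABET))
    matrix.loc[0] = 0.0  # acceptor handled by the acceptor preference
    return matrix


def generate_kinase_library(n_kinases: int, seed: int) -> list[KinaseMotifModel]:
    """A synthetic kinase library with planted consensus models.

    The first model carries the AMPK consensus preferences (hydrophobic
    at -5 and +4, basic at -4 and -3) and the second the ROCK
    preferences (basic at -2 and -3); every other kinase gets 1-3
    strongly preferred (position, residue) pairs (log-odds >= 2) on a
    near-uniform background.  Same seed, same matrices.
    """
    names = kinase_names(n_kinases)
    rng = np.random.default_rng(seed)
    models = []
    for i, name in enumerate(names):
        matrix = _blank_matrix(rng)
        if name == AMPK_LIKE:
            for res in HYDROPHOBIC:
                matrix.at[-5, res] = 2.0
                matrix.at[4, res] = 2.0
            for res in BASIC_AMPK:
                matrix.at[-4, res] = 2.0
                matrix.at[-3, res] = 2.0
            motif_class = "CAMK"
        elif name == ROCK_LIKE:
            for res in BASIC_ROCK:
                matrix.at[-2, res] = 2.0
                matrix.at[-3, res] = 2.0
            motif_class = "AGC"
        else:
            n_pref = int(rng.integers(1, 4))
            positions = rng.choice([p for p in POSITIONS if p != 0],
                                   size=n_pref, replace=False)
            for pos in positions:
                res = ALPHABET[int(rng.integers(len(ALPHABET)))]
                matrix.at[int(pos), res] = float(rng.uniform(2.0, 3.0))
            motif_class = _MOTIF_CLASSES[int(rng.integers(len(_MOTIF_CLASSES)))]
        pref_s = float(rng.uniform(0.3, 0.7))
        models.append(KinaseMotifModel(
            name=name, matrix=matrix, motif_class=motif_class,
            acceptor_pref={"S": pref_s, "T": 1.0 - pref_s},
        ))
    return models


# -- phosphoproteome -----------------------------------------------------

def _sample_window(model: KinaseMotifModel, rng: np.random.Generator) -> str:
    """Draw a window from the PSSM as a per-position categorical."""
    residues = []
    for pos in POSITIONS:
        if pos == 0:
            labels = sorted(model.acceptor_pref)
            probs = np.array([model.acceptor_pref[r] for r in labels])
            residues.append(labels[int(rng.choice(len(labels), p=probs))])
            continue
        weights = np.exp(model.matrix.loc[pos].to_numpy(dtype=float))
        probs = weights / weights.sum()
        residues.append(ALPHABET[int(rng.choice(len(ALPHABET), p=probs))])
    return "".join(residues)


def _null_window(rng: np.random.Generator) -> str:
    """Uniform window over the 20-residue alphabet with an S/T acceptor."""
    residues = [ALPHABET[int(i)] for i in rng.integers(len(ALPHABET),
                                                       size=WINDOW_LENGTH)]
    residues[CENTER_INDEX] = "ST"[int(rng.integers(2))]
    return "".join(residues)


def generate_phosphoproteome(
    truth: SyntheticTruth,
    library: list[KinaseMotifModel],
    config: RunConfig,
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """A differential phosphosite table with planted regulated substrates.

    Planted substrates of up-active kinases receive log2FC ~
    Normal(+effect_size, noise_sd) (down-active analogously negative)
    and windows sampled from the owning kinase's PSSM; null sites get
    log2FC ~ Normal(0, noise_sd) and uniform windows.  Raw p-values are
    the two-sided normal tails of log2FC / noise_sd and are BH-adjusted
    across the table.  Returns the table and the truth with the planted
    substrate map filled in.
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in library}
    for kinase in truth.active_kinases_up | truth.active_kinases_down:
        if kinase not in by_name:
            raise ParameterError(f"active kinase {kinase!r} is not in the library")

    active = sorted(truth.active_kinases_up) + sorted(truth.active_kinases_down)
    n_reg = int(round(truth.fraction_regulated * truth.n_sites)) if active else 0
    if n_reg > truth.n_sites:
        raise ParameterError("requested planted substrates exceed n_sites")
    if n_reg > 0 and truth.effect_size < config.log2fc_min:
        raise ParameterError(
            f"effect size {truth.effect_size} below the call threshold "
            f"{config.log2fc_min}; planted sites would not be callable"
        )

    proteins = [f"P{i:04d}" for i in range(truth.n_proteins)]
    owner_protein = rng.integers(truth.n_proteins, size=truth.n_sites)
    # unique 1-based positions per protein: disjoint blocks per occurrence
    seen: dict[int, int] = {}
    positions = np.empty(truth.n_sites, dtype=int)
    for i, p in enumerate(owner_protein):
        k = seen.get(int(p), 0)
        positions[i] = 20 * k + int(rng.integers(1, 20))
        seen[int(p)] = k + 1

    planted_idx = rng.choice(truth.n_sites, size=n_reg, replace=False) if n_reg else np.array([], dtype=int)
    owner_kinase = np.full(truth.n_sites, "", dtype=object)
    planted_map: dict[str, set] = {k: set() for k in active}
    if n_reg:
        shares = np.array_split(planted_idx, len(active))
        for kinase, idx in zip(active, shares):
            for i in idx:
                owner_kinase[i] = kinase

    windows = np.empty(truth.n_sites, dtype=object)
    log2fc = rng.normal(0.0, truth.noise_sd, size=truth.n_sites)
    for i in range(truth.n_sites):
        kinase = owner_kinase[i]
        if kinase:
            windows[i] = _sample_window(by_name[kinase], rng)
            sign = 1.0 if kinase in truth.active_kinases_up else -1.0
            log2fc[i] = rng.normal(sign * truth.effect_size, truth.noise_sd)
            planted_map[kinase].add((proteins[owner_protein[i]], int(positions[i])))
        else:
            windows[i] = _null_window(rng)

    raw_p = 2.0 * norm.sf(np.abs(log2fc) / truth.noise_sd)
    raw_p = np.clip(raw_p, np.nextafter(0.0, 1.0), 1.0)
    adj_p = np.clip(bh_adjust(raw_p), np.nextafter(0.0, 1.0), 1.0)

    residues = [w[CENTER_INDEX] for w in windows]
    table = pd.DataFrame({
        "site": [site_id(proteins[p], r, q) for p, r, q in
                 zip(owner_protein, residues, positions)],
        "protein": [proteins[p] for p in owner_protein],
        "position": positions,
        "residue": residues,
        "window": windows,
        "comparison": truth.comparison,
        "log2fc": log2fc,
        "adj_p": adj_p,
    })
    return table, replace(truth, planted_substrates=planted_map)


# -- annotations ---------------------------------------------------------

def generate_annotations(
    truth: SyntheticTruth,
    seed: int,
    evidence_fraction: float = 0.6,
    interaction_fraction: float = 0.5,
    n_random_sets: int = 20,
    random_set_size: tuple[int, int] = (10, 30),
) -> tuple[pd.DataFrame, pd.DataFrame, list[PathwayGeneSet], pd.DataFrame, SyntheticTruth]:
    """Evidence, interaction, gene-set and dependency tables for a truth.

    A configurable fraction of planted kinase-substrate pairs receive
    in vitro / in vivo evidence flags; interaction reference counts are
    geometric (support >= 1); one planted pathway per active kinase
    contains that kinase's substrate proteins; the substrate proteins of
    the first up-active kinase are designated essential with a margin
    below the -0.5 cutoff, all other genes draw Chronos ~ Normal(0, 0.3).
    """
    if not 0 <= evidence_fraction <= 1 or not 0 <= interaction_fraction <= 1:
        raise ParameterError("evidence/interaction fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(truth.n_proteins)]

    evidence_rows, interaction_rows = [], []
    for kinase in sorted(truth.planted_substrates):
        for protein, position in sorted(truth.planted_substrates[kinase]):
            if rng.random() < evidence_fraction:
                in_vitro = bool(rng.random() < 0.7)
                in_vivo = bool(rng.random() < 0.7) or not in_vitro
                evidence_rows.append(dict(kinase=kinase, protein=protein,
                                          position=position,
                                          in_vitro=int(in_vitro),
                                          in_vivo=int(in_vivo)))
            if rng.random() < interaction_fraction:
                interaction_rows.append(dict(kinase=kinase, protein=protein,
                                             n_refs=int(rng.geometric(0.5))))
    evidence = pd.DataFrame(evidence_rows,
                            columns=["kinase", "protein", "position",
                                     "in_vitro", "in_vivo"])
    interactions = (pd.DataFrame(interaction_rows,
                                 columns=["kinase", "protein", "n_refs"])
                    .drop_duplicates(subset=["kinase", "protein"]))

    gene_sets: list[PathwayGeneSet] = []
    planted_pathways: dict[str, frozenset] = {}
    for kinase in sorted(truth.planted_substrates):
        members = {p for p, _ in truth.planted_substrates[kinase]}
        extra = rng.choice(truth.n_proteins, size=min(5, truth.n_proteins),
                           replace=False)
        members |= {proteins[i] for i in extra}
        name = f"PLANTED_{kinase}"
        planted_pathways[name] = frozenset(members)
        gene_sets.append(PathwayGeneSet(name, f"planted substrates of {kinase}",
                                        frozenset(members)))
    lo, hi = random_set_size
    for j in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(proteins[i] for i in
                            rng.choice(truth.n_proteins, size=size, replace=False))
        gene_sets.append(PathwayGeneSet(f"RANDOM_{j:02d}", "decoy set", members))

    up_active = sorted(truth.active_kinases_up)
    if up_active and truth.planted_substrates.get(up_active[0]):
        essential = {p for p, _ in truth.planted_substrates[up_active[0]]}
    else:
        essential = {proteins[i] for i in
                     rng.choice(truth.n_proteins,
                                size=min(10, truth.n_proteins), replace=False)}
    chronos = rng.normal(0.0, 0.3, size=truth.n_proteins)
    dependency = pd.DataFrame({"gene": proteins, "chronos": chronos})
    mask = dependency["gene"].isin(essential)
    dependency.loc[mask, "chronos"] = np.minimum(
        rng.normal(-1.0, 0.15, size=int(mask.sum())), -0.6)

    updated = replace(truth, essential_genes=frozenset(essential),
                      planted_pathways=planted_pathways)
    return evidence, interactions, gene_sets, dependency, updated
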