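"""Kinase motif models and phosphosite window scoring.

A phosphosite is represented by a 10-residue sequence window spanning
positions -5..+4 around the phospho-acceptor (acceptor at position 0,
string index 5).  Windows that run off a protein terminus are padded
with ``_``; padded positions contribute nothing to any score.

Two kinds of motif matching are provided:

* consensus matchers for the ROCK (basic residue at -2 or -3) and AMPK
  (hydrophobic at -5/+4, basic at -4/-3) substrate motifs;
* position-specific scoring matrices (PSSMs), one per kinase, whose
  additive log-odds score is converted into an empirical percentile
  against a background sample of window scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The 20 standard amino acids, alphabetical one-letter codes.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Character marking window positions beyond a protein terminus.
PAD = "_"
#: Window positions relative to the acceptor.
POSITIONS = tuple(range(-5, 5))
#: Window string length and acceptor index within it.
WINDOW_LENGTH = len(POSITIONS)
CENTER_INDEX = POSITIONS.index(0)

#: Residue classes used by the consensus motifs.
BASIC_ROCK = frozenset("RK")          # beta in the ROCK consensus
BASIC_AMPK = frozenset("RKH")         # beta in the AMPK consensus
HYDROPHOBIC = frozenset("MLIFV")      # phi in the AMPK consensus
ACCEPTORS = frozenset("STY")

_RES_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_RES_INDEX[PAD] = len(ALPHABET)  # pad maps to an all-zero matrix column


def validate_window(window: str) -> None:
    """Check length, alphabet and a non-pad acceptor; raise ValidationError."""
    if len(window) != WINDOW_LENGTH:
        raise ValidationError(
            f"window {window!r} has length {len(window)}, expected {WINDOW_LENGTH}"
        )
    bad = set(window) - set(ALPHABET) - {PAD}
    if bad:
        raise ValidationError(f"window {window!r} contains invalid characters {sorted(bad)}")
    if window[CENTER_INDEX] == PAD:
        raise ValidationError(f"window {window!r} has a padded acceptor position")


def window_residue(window: str, position: int) -> str:
    """Residue at a -5..+4 position of a validated window."""
    return window[POSITIONS.index(position)]


def match_rock_motif(window: str) -> bool:
    """True when the window fits the ROCK consensus (bXpS/T or bXXpS/T).

    A basic residue (R/K) at -2 or at -3 with a serine/threonine
    acceptor.  Padded positions never match; a tyrosine acceptor
    returns False because the motif requires pS/T.
    """
    validate_window(window)
    if window[CENTER_INDEX] not in "ST":
        return False
    return (
        window_residue(window, -2) in BASIC_ROCK
        or window_residue(window, -3) in BASIC_ROCK
    )


def match_ampk_motif(window: str, strict: bool = True) -> bool:
    """True when the window fits the AMPK consensus (phi-beta-beta-X-X-pS/T-X-X-X-phi).

    Strict mode requires hydrophobic (M/L/I/F/V) at -5, basic (R/K/H) at
    both -4 and -3, and hydrophobic at +4.  Relaxed mode accepts the
    common variants: hydrophobic at -5 or +4, and basic at -3.
    """
    validate_window(window)
    if window[CENTER_INDEX] not in "ST":
        return False
    phi_m5 = window_residue(window, -5) in HYDROPHOBIC
    phi_p4 = window_residue(window, +4) in HYDROPHOBIC
    beta_m4 = window_residue(window, -4) in BASIC_AMPK
    beta_m3 = window_residue(window, -3) in BASIC_AMPK
    if strict:
        return phi_m5 and beta_m4 and beta_m3 and phi_p4
    return (phi_m5 or phi_p4) and beta_m3


@dataclass
class SiteKinaseScore:
    """One kinase's score for one phosphosite."""

    site: str
    kinase: str
    raw: float
    percentile: float  # 0-100 scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValidationError(
                f"percentile must be within [0, 100], got {self.percentile}"
            )


@dataclass
class KinaseMotifModel:
    """A kinase's substrate-specificity model.

    Parameters
    ----------
    name : str
        Kinase name.
    matrix : pandas.DataFrame
        Log-odds scores indexed by position (-5..+4) with one column per
        residue in :data:`ALPHABET`.  The acceptor row (position 0) is
        ignored by scoring; acceptor preference is modelled separately.
    acceptor_pref : dict
        Probability over {S, T} for the acceptor residue.
    motif_class : str
        Free-text phylogenetic/motif class label (input annotation).
    background : numpy.ndarray, optional
        Sorted raw scores of reference windows used for percentile
        lookup.  Usually set from the analyzed dataset itself via
        :func:`score_matrix`.
    """

    name: str
    matrix: pd.DataFrame
    acceptor_pref: dict[str, float] = field(default_factory=lambda: {"S": 0.5, "T": 0.5})
    motif_class: str = ""
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = self.matrix.reindex(index=list(POSITIONS), columns=list(ALPHABET))
        if self.matrix.isna().any().any():
            raise ValidationError(
                f"PSSM for {self.name} is missing positions or residues"
            )
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValidationError(f"PSSM for {self.name} contains non-finite scores")
        total = sum(self.acceptor_pref.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValidationError(
                f"acceptor preference for {self.name} must sum to 1, got {total}"
            )
        if set(self.acceptor_pref) - {"S", "T"}:
            raise ValidationError("acceptor preference is defined over {S, T} only")
        if self.background is not None:
            self.set_background(self.background)

    # -- scoring ---------------------------------------------------------

    def _lookup(self) -> np.ndarray:
        """(positions x residues+pad) score array; pad column is zero."""
        arr = np.zeros((WINDOW_LENGTH, len(ALPHABET) + 1))
        arr[:, : len(ALPHABET)] = self.matrix.to_numpy()
        # acceptor handled through acceptor_pref, not the matrix row
        arr[CENTER_INDEX, :] = 0.0
        for res, pref in self.acceptor_pref.items():
            arr[CENTER_INDEX, _RES_INDEX[res]] = math.log(pref) if pref > 0 else -np.inf
        return arr

    def score_window(self, window: str) -> float:
        """Additive log-odds score of one window (pads contribute 0)."""
        validate_window(window)
        acceptor = window[CENTER_INDEX]
        if acceptor not in self.acceptor_pref:
            raise ValidationError(
                f"acceptor {acceptor!r} not scoreable by {self.name} "
                f"(expects one of {sorted(self.acceptor_pref)})"
            )
        lookup = self._lookup()
        idx = [_RES_INDEX[res] for res in window]
        return float(lookup[np.arange(WINDOW_LENGTH), idx].sum())

    def set_background(self, scores: np.ndarray) -> None:
        """Attach a (sorted copy of a) background raw-score sample."""
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValidationError("background sample must be non-empty")
        if not np.isfinite(scores).all():
            raise ValidationError("background sample must be finite")
        self.background = np.sort(scores)

    def percentile(self, raw: float) -> float:
        """Empirical percentile of a raw score in the background (midpoint rule)."""
        if self.background is None:
            raise ValidationError(f"model {self.name} has no background sample")
        left = np.searchsorted(self.background, raw, side="left")
        right = np.searchsorted(self.background, raw, side="right")
        return float(100.0 * (left + right) / (2 * self.background.size))

    def score_site(self, site: str, window: str) -> SiteKinaseScore:
        raw = self.score_window(window)
        return SiteKinaseScore(site=site, kinase=self.name, raw=raw,
                               percentile=self.percentile(raw))


def encode_windows(windows: list[str]) -> np.ndarray:
    """Validate and encode windows into an (n, 10) residue-index array."""
    for window in windows:
        validate_window(window)
    return np.array([[_RES_INDEX[res] for res in window] for window in windows],
                    dtype=np.intp)


def score_matrix(
    windows: list[str],
    models: list[KinaseMotifModel],
    set_background: bool = True,
) -> pd.DataFrame:
    """Raw scores of every window against every model (sites x kinases).

    When ``set_background`` is true (the default) each model's background
    sample is set to its own column of scores, making subsequent
    percentiles dataset-internal.
    """
    encoded = encode_windows(windows)
    columns = {}
    for model in models:
        lookup = model._lookup()
        scores = lookup[np.arange(WINDOW_LENGTH)[None, :], encoded].sum(axis=1)
        if not np.isfinite(scores).all():
            raise ValidationError(
                f"model {model.name} cannot score an acceptor in these windows"
            )
        columns[model.name] = scores
        if set_background:
            model.set_background(scores)
    return pd.DataFrame(columns, index=pd.Index(range(len(windows))))


def percentile_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    """Columnwise empirical percentiles (0-100) with midpoint tie handling.

    Each column is its own background, matching the dataset-internal
    percentile convention: percentile = 100 * (rank - 0.5) / n with
    average ranks for ties.
    """
    from scipy.stats import rankdata

    n = raw.shape[0]
    ranks = np.apply_along_axis(lambda col: rankdata(col, method="average"), 0,
                                raw.to_numpy())
    return pd.DataFrame(100.0 * (ranks - 0.5) / n, index=raw.index,
                        columns=raw.columns)


def top_kinases_for_site(scores: list[SiteKinaseScore], k: int) -> list[SiteKinaseScore]:
    """The k highest-percentile kinases for one site.

    Boundary ties are broken by raw score (higher wins), then by kinase
    name (lexicographically smaller wins), so results are deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if not scores:
        return []
    sites = {s.site for s in scores}
    if len(sites) != 1:
        raise ValidationError(f"scores must cover a single site, got {sorted(sites)}")
    ordered = sorted(scores, key=lambda s: (-s.percentile, -s.raw, s.kinase))
    return ordered[: min(k, len(ordered))]


def top_kinase_sets(percentiles: pd.DataFrame, raw: pd.DataFrame,
                    k: int) -> dict[int, frozenset[str]]:
    """Per-site top-k kinase membership, vectorized over a score matrix.

    Ranking and tie-breaks match :func:`top_kinases_for_site`.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    kinases = np.array(percentiles.columns)
    name_rank = np.argsort(np.argsort(kinases))  # lexicographic rank per column
    out: dict[int, frozenset[str]] = {}
    perc = percentiles.to_numpy()
    rawv = raw.to_numpy()
    for i, site in enumerate(percentiles.index):
        order = np.lexsort((name_rank, -rawv[i], -perc[i]))
        out[site] = frozenset(kinases[order[: min(k, kinases.size)]])
    return out
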