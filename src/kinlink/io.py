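"""Readers and writers for every tabular and set format the pipeline uses.

All tables are UTF-8 TSV with a header row.  Gene sets use the standard
GMT format.  Networks export to GraphML (validated by networkx) or SIF;
both round-trip node/edge identity and edge weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .errors import FormatError, SchemaError, ValidationError
from .flux import FluxTrace
from .motifs import (ALPHABET, CENTER_INDEX, KinaseMotifModel, PAD, POSITIONS,
                     validate_window)

logger = logging.getLogger(__name__)

PHOSPHOSITE_COLUMNS = ["site", "protein", "position", "residue", "window",
                       "comparison", "log2fc", "adj_p"]
EVIDENCE_COLUMNS = ["kinase", "protein", "position", "in_vitro", "in_vivo"]
INTERACTION_COLUMNS = ["kinase", "protein", "n_refs"]
DEPENDENCY_COLUMNS = ["gene", "chronos"]


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PathwayGeneSet:
    """A named protein set (one GMT line)."""

    name: str
    description: str
    members: frozenset


def site_id(protein: str, residue: str, position: int) -> str:
    """Canonical phosphosite key, e.g. ``PPP1R12A_T696``."""
    return f"{protein}_{residue}{int(position)}"


# -- phosphosite tables --------------------------------------------------

def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns {missing}")


def read_phosphosite_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a phosphosite TSV.

    Every window must be a 10-character string over the 20 amino acids
    plus the ``_`` terminus pad, centered on an S/T/Y acceptor matching
    the ``residue`` column.  Malformed rows are reported with their line
    numbers; duplicate (protein, position, residue) keys within a
    comparison are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "residue": str,
                                            "window": str, "comparison": str})
    _require_columns(df, [c for c in PHOSPHOSITE_COLUMNS if c != "site"],
                     f"phosphosite table {path}")
    problems = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            validate_window(row.window)
            if row.residue not in "STY":
                raise ValidationError(
                    f"acceptor residue {row.residue!r} not in {{S, T, Y}}"
                )
            if row.window[CENTER_INDEX] != row.residue:
                raise ValidationError(
                    f"window center {row.window[CENTER_INDEX]!r} does not match "
                    f"acceptor {row.residue!r}"
                )
            if not 0 < row.adj_p <= 1:
                raise ValidationError(f"adjusted p {row.adj_p} outside (0, 1]")
        except ValidationError as exc:
            problems.append(f"line {i}: {exc}")
    if problems:
        raise ValidationError(
            "malformed phosphosite rows:\n" + "\n".join(problems)
        )
    if "site" not in df.columns:
        df.insert(0, "site", [site_id(p, r, q) for p, r, q in
                              zip(df["protein"], df["residue"], df["position"])])
    dup = df.duplicated(subset=["protein", "position", "residue", "comparison"])
    if dup.any():
        raise ValidationError(
            f"duplicate (protein, position, residue) keys at rows "
            f"{list(df.index[dup])}"
        )
    return df


def write_phosphosite_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, required, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, what)
    return df


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, EVIDENCE_COLUMNS, f"evidence table {path}")


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, INTERACTION_COLUMNS, f"interaction table {path}")
    if (df["n_refs"] < 0).any():
        raise ValidationError("interaction reference counts must be >= 0")
    return df


def read_dependency_table(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, DEPENDENCY_COLUMNS, f"dependency table {path}")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- GMT gene sets -------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read a GMT file: name, description, then tab-separated members.

    Duplicate members within a set are de-duplicated; empty sets and
    lines with fewer than three fields are rejected.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 member, got {len(fields)} fields"
                )
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            sets.append(PathwayGeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: list[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def gene_set_dict(sets: list[PathwayGeneSet]) -> dict[str, frozenset]:
    return {s.name: s.members for s in sets}


# -- PSSM libraries ------------------------------------------------------

def write_pssm_library(models: list[KinaseMotifModel], path: str | Path) -> None:
    """Long-format PSSM TSV: kinase, motif class, acceptor preferences,
    position, and one column per residue."""
    rows = []
    for model in models:
        for pos in POSITIONS:
            row = {"kinase": model.name, "motif_class": model.motif_class,
                   "acceptor_S": model.acceptor_pref.get("S", 0.0),
                   "acceptor_T": model.acceptor_pref.get("T", 0.0),
                   "position": pos}
            row.update({aa: model.matrix.at[pos, aa] for aa in ALPHABET})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pssm_library(path: str | Path) -> list[KinaseMotifModel]:
    df = read_tsv(path, ["kinase", "position", *ALPHABET], f"PSSM library {path}")
    models = []
    for kinase, group in df.groupby("kinase", sort=True):
        matrix = group.set_index("position")[list(ALPHABET)].rename_axis(None)
        pref = {}
        for res in ("S", "T"):
            col = f"acceptor_{res}"
            if col in group.columns:
                value = float(group[col].iloc[0])
                if value > 0:
                    pref[res] = value
        if not pref:
            pref = {"S": 0.5, "T": 0.5}
        motif_class = ""
        if "motif_class" in group.columns and not group["motif_class"].isna().all():
            motif_class = str(group["motif_class"].iloc[0])
        models.append(KinaseMotifModel(name=str(kinase), matrix=matrix,
                                       acceptor_pref=pref,
                                       motif_class=motif_class))
    return models


# -- flux traces ---------------------------------------------------------

def read_flux_trace(path: str | Path, modality: str) -> FluxTrace:
    """Trace TSV with columns time, rate and an optional event column.

    An event label on a row means that injection happened between the
    previous measurement and this one; the injection time is recorded as
    the midpoint of the two measurement times.
    """
    df = read_tsv(path, ["time", "rate"], f"flux trace {path}")
    events = []
    if "event" in df.columns:
        for i, label in enumerate(df["event"]):
            if isinstance(label, str) and label:
                if i == 0:
                    raise ValidationError(
                        "an injection cannot precede the first measurement"
                    )
                t = (df["time"].iloc[i - 1] + df["time"].iloc[i]) / 2.0
                events.append((label, float(t)))
    return FluxTrace(modality=modality, times=df["time"].to_numpy(),
                     rates=df["rate"].to_numpy(), events=events)


def write_flux_trace(trace: FluxTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time": trace.times, "rate": trace.rates, "event": ""})
    for label, t in trace.events:
        after = np.nonzero(trace.times > t)[0]
        if after.size:
            df.loc[after[0], "event"] = label
    df.to_csv(path, sep="\t", index=False)


# -- networks ------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a scored kinase-substrate network as GraphML or SIF."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in graph.edges(data=True):
                rel = data.get("direction", "interacts")
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in nx.isolates(graph):
                fh.write(f"{node}\n")
    else:
        raise FormatError(f"unknown network format {fmt!r} (use graphml or sif)")


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        graph = nx.DiGraph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    graph.add_node(fields[0])
                elif len(fields) >= 3:
                    graph.add_edge(fields[0], fields[2], direction=fields[1])
        return graph
    raise FormatError(f"unknown network format {fmt!r} (use graphml or sif)")


def write_json(data, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
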