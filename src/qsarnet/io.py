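"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects:

* descriptor CSV — PaDEL style: header row of descriptor names, first
  column ``Name`` holds compound identifiers; non-numeric cells are parsed
  as NaN and reported with their location.
* labels CSV — columns ``compound,property,class`` with ``+``/``-`` calls.
* GMT — ``term<TAB>description<TAB>member...`` one term per line.
* edge TSV — ``node1<TAB>node2<TAB>combined_score`` with a header;
  duplicate undirected edges are deduplicated with a warning.
* SIF — ``node1<TAB>interaction<TAB>node2``; carries no score, edges get
  combined score 1.0.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .classifiers import PropertyLabels
from .enrich import AnnotationSets
from .network import make_graph, normalize_id
from .prep import DescriptorMatrix


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------- descriptors

def read_descriptor_csv(path) -> DescriptorMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no descriptor columns")
    bad_cells = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        for i in np.flatnonzero(newly_bad.to_numpy()):
            bad_cells.append((i + 2, col))  # +2: header line and 1-based
        df[col] = coerced
    if bad_cells:
        warnings.warn(
            f"{path}: {len(bad_cells)} non-numeric cell(s), first at line "
            f"{bad_cells[0][0]} column {bad_cells[0][1]!r}; parsed as NaN"
        )
    return DescriptorMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


def write_descriptor_csv(X: DescriptorMatrix, path) -> None:
    df = X.to_frame()
    df.index.name = "Name"
    df.to_csv(path)


# --------------------------------------------------------------------- labels

def read_labels_csv(path, property: str | None = None) -> PropertyLabels:
    df = pd.read_csv(path)
    required = {"compound", "property", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: labels CSV needs columns {sorted(required)}")
    if property is not None:
        df = df[df["property"] == property]
        if df.empty:
            raise FormatError(f"{path}: no rows for property {property!r}")
    else:
        props = df["property"].unique()
        if len(props) > 1:
            raise FormatError(f"{path}: multiple properties {list(props)}; pass property=")
        property = props[0]
    return PropertyLabels(list(df["compound"].astype(str)), str(property), list(df["class"]))


def write_labels_csv(labels: PropertyLabels, path) -> None:
    pd.DataFrame({
        "compound": labels.compound_ids,
        "property": labels.property,
        "class": labels.classes,
    }).to_csv(path, index=False)


# ----------------------------------------------------------------------- GMT

def read_gmt(path, namespace: str = "pathway") -> AnnotationSets:
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description, members")
            term, _desc, *members = parts
            members = [m for m in members if m]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = set(members)
    background = set().union(*terms.values()) if terms else set()
    return AnnotationSets(background, terms, namespace=namespace)


def write_gmt(ann: AnnotationSets, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(ann.terms):
            members = "\t".join(sorted(ann.terms[term]))
            fh.write(f"{term}\t{descriptions.get(term, 'na')}\t{members}\n")


# --------------------------------------------------------------------- graphs

def read_edge_tsv(path) -> nx.Graph:
    edges = []
    seen: set[tuple[str, str]] = set()
    dups = 0
    with open(path) as fh:
        header = fh.readline()
        if "node1" not in header:
            raise FormatError(f"{path}:1: expected header 'node1\\tnode2\\tcombined_score'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            u, v = normalize_id(parts[0]), normalize_id(parts[1])
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad combined score {parts[2]!r}") from exc
            key = (min(u, v), max(u, v))
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            edges.append((u, v, w))
    if dups:
        warnings.warn(f"{path}: deduplicated {dups} duplicate undirected edge(s)")
    return make_graph(edges)


def write_edge_tsv(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('combined_score', 1.0)}\n")


def read_sif(path) -> nx.Graph:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: SIF line needs node, interaction, node(s)")
            u, _rel, *targets = parts
            for v in targets:
                edges.append((u, v, 1.0))
    # deduplicate undirected pairs, keep first
    uniq, seen = [], set()
    for u, v, w in edges:
        key = tuple(sorted((normalize_id(u), normalize_id(v))))
        if key not in seen:
            seen.add(key)
            uniq.append((u, v, w))
    return make_graph(uniq)


def read_graph(path) -> nx.Graph:
    path = Path(path)
    if path.suffix.lower() == ".sif":
        return read_sif(path)
    return read_edge_tsv(path)


# ----------------------------------------------------------------------- YAML

def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
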