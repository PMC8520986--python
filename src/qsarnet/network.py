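"""Network-pharmacology target screening.

Pharmacophore-mapping fit scores are filtered per compound (retain targets
scoring ≥ 4.0, falling back to ≥ 3.5 for compounds with no such target),
compound targets are intersected with disease targets, and the common-target
PPI graph is characterised with the four topological features DV (degree),
NDD (degree distribution), NBC (normalized betweenness) and NCC (closeness),
plus whole-graph centralization and heterogeneity. Key targets are the
nodes whose DV, NBC and NCC all strictly exceed the network averages.

Centrality conventions follow Cytoscape NetworkAnalyzer: betweenness is
normalized by (N−1)(N−2)/2; closeness is computed within each connected
component as (reachable count)/(sum of geodesic distances); centralization
is (N/(N−2)) × (max DV/(N−1) − density); heterogeneity is the coefficient
of variation of the degree sequence (population variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def normalize_id(identifier: str) -> str:
    """Canonical target identifier: trimmed, upper-case."""
    return str(identifier).strip().upper()


@dataclass
class FitScoreTable:
    """(compound, target, fit score) rows from pharmacophore mapping."""

    rows: pd.DataFrame  # columns: compound_id, target_id, fit_score

    def __post_init__(self) -> None:
        df = self.rows.copy()
        df.columns = ["compound_id", "target_id", "fit_score"]
        df["compound_id"] = df["compound_id"].astype(str).str.strip()
        df["target_id"] = df["target_id"].map(normalize_id)
        df["fit_score"] = df["fit_score"].astype(float)
        if not np.isfinite(df["fit_score"]).all():
            raise ValueError("fit scores must be finite")
        if (df["fit_score"] < 0).any():
            raise ValueError("fit scores must be non-negative")
        if df.duplicated(["compound_id", "target_id"]).any():
            dups = df[df.duplicated(["compound_id", "target_id"])]
            raise ValueError(
                f"duplicate (compound, target) rows, e.g. "
                f"{tuple(dups.iloc[0][['compound_id', 'target_id']])}"
            )
        self.rows = df


def filter_fit_scores(
    table: FitScoreTable, threshold: float = 4.0, fallback: float = 3.5
) -> dict[str, set[str]]:
    """Per-compound target retention with the two-tier score rule.

    Targets scoring ≥ ``threshold`` are retained; a compound with none such
    falls back to targets scoring ≥ ``fallback``. A compound failing both
    tiers maps to the empty set.
    """
    if threshold <= 0 or fallback <= 0:
        raise ValueError("thresholds must be positive")
    if fallback >= threshold:
        raise ValueError("fallback must be below the primary threshold")
    out: dict[str, set[str]] = {}
    for compound, grp in table.rows.groupby("compound_id", sort=False):
        hits = set(grp.loc[grp["fit_score"] >= threshold, "target_id"])
        if not hits:
            hits = set(grp.loc[grp["fit_score"] >= fallback, "target_id"])
        out[compound] = hits
    return out


def intersect_targets(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], tuple[int, int, int]]:
    """Exact intersection of normalized identifier sets.

    Returns the overlap and the report triple (|A|, |B|, |A∩B|).
    """
    a = {normalize_id(x) for x in set_a}
    b = {normalize_id(x) for x in set_b}
    overlap = a & b
    return overlap, (len(a), len(b), len(overlap))


def make_graph(edges, nodes=None) -> nx.Graph:
    """Simple undirected weighted graph from (u, v, combined_score) triples.

    Self-loops are rejected; duplicate undirected edges keep the first
    weight seen. Extra isolated ``nodes`` may be declared explicitly.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(normalize_id(n) for n in nodes)
    for u, v, w in edges:
        u, v = normalize_id(u), normalize_id(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        w = float(w)
        if not (0.0 < w <= 1.0):
            raise ValueError(f"combined score must be in (0, 1], got {w} for ({u}, {v})")
        if not g.has_edge(u, v):
            g.add_edge(u, v, combined_score=w)
    return g


@dataclass
class TopologyTable:
    """Per-node and whole-graph topological features."""

    per_node: pd.DataFrame  # index: node; columns: DV, NBC, NCC
    degree_distribution: dict[int, int]  # degree -> node count (NDD)
    centralization: float  # NaN when N < 3
    heterogeneity: float
    mean_dv: float
    mean_nbc: float
    mean_ncc: float

    @property
    def n_nodes(self) -> int:
        return len(self.per_node)

    @property
    def n_edges(self) -> int:
        return int(round(self.per_node["DV"].sum() / 2))


def topology_metrics(g: nx.Graph, drop_isolated: bool = False) -> TopologyTable:
    """DV/NBC/NCC per node plus NDD, centralization and heterogeneity.

    Edge weights are carried for rendering semantics only; all metrics are
    computed on the unweighted topology. With ``drop_isolated`` the
    degree-0 nodes are removed before anything is computed.
    """
    g = g.copy()
    if any(u == v for u, v in g.edges()):
        raise ValueError("graph must be simple (no self-loops)")
    if drop_isolated:
        g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")

    dv = dict(g.degree())
    nbc = nx.betweenness_centrality(g, normalized=True) if n > 2 else {v: 0.0 for v in nodes}
    # closeness within each connected component: (n_c - 1) / sum of distances
    ncc: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for v in comp:
            if len(comp) == 1:
                ncc[v] = 0.0
            else:
                total = sum(nx.single_source_shortest_path_length(sub, v).values())
                ncc[v] = (len(comp) - 1) / total

    per_node = pd.DataFrame(
        {"DV": [dv[v] for v in nodes],
         "NBC": [nbc[v] for v in nodes],
         "NCC": [ncc[v] for v in nodes]},
        index=nodes,
    )
    degrees = per_node["DV"].to_numpy(dtype=float)
    ndd: dict[int, int] = {}
    for d in sorted(set(int(x) for x in degrees)):
        ndd[d] = int((degrees == d).sum())

    if n < 3:
        centralization = math.nan
    else:
        density = nx.density(g)
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    mean_dv = float(degrees.mean())
    heterogeneity = float(np.sqrt(degrees.var()) / mean_dv) if mean_dv > 0 else math.nan

    return TopologyTable(
        per_node=per_node,
        degree_distribution=ndd,
        centralization=float(centralization),
        heterogeneity=heterogeneity,
        mean_dv=mean_dv,
        mean_nbc=float(per_node["NBC"].mean()),
        mean_ncc=float(per_node["NCC"].mean()),
    )


@dataclass
class KeyTargetSet:
    """Nodes passing the triple above-average screen, with thresholds."""

    members: set[str]
    avg_dv: float
    avg_nbc: float
    avg_ncc: float

    def to_frame(self, topology: TopologyTable) -> pd.DataFrame:
        df = topology.per_node.loc[sorted(self.members)].copy()
        df.attrs["thresholds"] = {
            "avg_DV": self.avg_dv, "avg_NBC": self.avg_nbc, "avg_NCC": self.avg_ncc
        }
        return df.sort_values("DV", ascending=False)


def screen_key_nodes(t: TopologyTable) -> KeyTargetSet:
    """Retain nodes whose DV, NBC and NCC all strictly exceed the averages.

    On a vertex-transitive graph every metric equals its average, so the
    strict screen is empty — this boundary behaviour is intentional.
    """
    df = t.per_node
    mask = (df["DV"] > t.mean_dv) & (df["NBC"] > t.mean_nbc) & (df["NCC"] > t.mean_ncc)
    return KeyTargetSet(
        members=set(df.index[mask]),
        avg_dv=t.mean_dv,
        avg_nbc=t.mean_nbc,
        avg_ncc=t.mean_ncc,
    )
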