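"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed, and every
output records its planted ground truth so downstream stages can be tested
against a known answer:

* a labelled descriptor matrix whose binary property labels follow a
  logistic model over a small planted subset of informative descriptors;
* random protein-interaction graphs (Erdős–Rényi or preferential-attachment
  hubs) with STRING-style combined-score edge weights;
* annotation term sets with exactly one term planted to overlap a hit list;
* pharmacophore fit-score tables whose planted compound–target pairs score
  above the retention threshold and whose noise pairs score below the
  fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .classifiers import NEG, POS, PropertyLabels
from .enrich import AnnotationSets
from .network import FitScoreTable
from .prep import DescriptorMatrix

GENERATORS = ("erdos_renyi", "preferential_attachment")


@dataclass
class SyntheticQsarSet:
    matrix: DescriptorMatrix
    labels: PropertyLabels
    informative_names: list[str]
    effect_size: float
    seed: int


@dataclass
class SyntheticNetworkSet:
    graph: nx.Graph
    generator: str
    params: dict[str, Any]
    seed: int


@dataclass
class SyntheticAnnotationSet:
    annotation: AnnotationSets
    planted_term: str
    hit_list: set[str]


def gen_descriptor_dataset(
    n_compounds: int,
    n_descriptors: int,
    n_informative: int,
    effect_size: float = 2.0,
    class_balance: float = 0.5,
    seed: int = 0,
    property: str = "OB",
    correlated_frac: float = 0.0,
    constant_frac: float = 0.0,
) -> SyntheticQsarSet:
    """Labelled descriptor matrix with a planted informative subset.

    Base descriptors are independent standard normal. Labels are Bernoulli
    with logit ``b + effect_size × Σ informative / √n_informative``; the
    intercept ``b`` is solved so the expected positive fraction equals
    ``class_balance``. ``correlated_frac`` / ``constant_frac`` of the
    columns are made near-duplicates of earlier columns / constants, to
    exercise the pruning rules, and are never informative.
    """
    if n_compounds < 4:
        raise ValueError("need at least 4 compounds")
    if not (0 < n_informative <= n_descriptors):
        raise ValueError("need 0 < n_informative <= n_descriptors")
    if not (0.0 < class_balance < 1.0):
        raise ValueError("class_balance must be in (0, 1)")
    if correlated_frac + constant_frac >= 1.0:
        raise ValueError("correlated_frac + constant_frac must leave room for base columns")

    rng = np.random.default_rng(seed)
    n_corr = int(round(correlated_frac * n_descriptors))
    n_const = int(round(constant_frac * n_descriptors))
    n_base = n_descriptors - n_corr - n_const
    if n_base < n_informative:
        raise ValueError("too few base columns for the requested informative subset")

    X = np.empty((n_compounds, n_descriptors))
    X[:, :n_base] = rng.standard_normal((n_compounds, n_base))
    for j in range(n_base, n_base + n_corr):
        src = rng.integers(0, n_base)
        X[:, j] = X[:, src] + 0.01 * rng.standard_normal(n_compounds)
    X[:, n_base + n_corr :] = rng.uniform(0, 10, size=n_const)  # constant per column

    names = [f"MD{j + 1:04d}" for j in range(n_descriptors)]
    info_idx = rng.choice(n_base, size=n_informative, replace=False)
    informative = [names[j] for j in sorted(info_idx)]

    score = effect_size * X[:, sorted(info_idx)].sum(axis=1) / np.sqrt(n_informative)

    def mean_prob(b: float) -> float:
        return float(expit(b + score).mean()) - class_balance

    b = brentq(mean_prob, -50, 50) if effect_size != 0 else float(np.log(class_balance / (1 - class_balance)))
    y01 = rng.random(n_compounds) < expit(b + score)
    labels = PropertyLabels(
        [f"C{i + 1:04d}" for i in range(n_compounds)],
        property,
        [POS if v else NEG for v in y01],
    )
    matrix = DescriptorMatrix(list(labels.compound_ids), names, X)
    return SyntheticQsarSet(matrix, labels, informative, effect_size, seed)


def gen_ppi_graph(
    n_nodes: int,
    generator: str = "erdos_renyi",
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> SyntheticNetworkSet:
    """Random simple undirected PPI-style graph with combined-score weights.

    ``erdos_renyi`` takes ``p`` (edge probability, default 0.1);
    ``preferential_attachment`` takes ``m`` (edges per new node, default 2)
    and yields hub structure. Weights are Uniform(0.4, 1.0] — the
    medium-to-high confidence range of STRING combined scores.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if generator == "erdos_renyi":
        p = params.setdefault("p", 0.1)
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    elif generator == "preferential_attachment":
        m = params.setdefault("m", 2)
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown generator {generator!r}; choose from {GENERATORS}")
    g = nx.relabel_nodes(g, {i: f"P{i + 1:04d}" for i in g.nodes()})
    for u, v in g.edges():
        g.edges[u, v]["combined_score"] = float(np.round(1.0 - 0.6 * rng.random(), 3))
    return SyntheticNetworkSet(g, generator, params, seed)


def gen_annotation_sets(
    background_size: int = 200,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (5, 25),
    hit_list_size: int = 10,
    planted_overlap: int = 6,
    seed: int = 0,
    background: list[str] | None = None,
    hit_list: set[str] | None = None,
) -> SyntheticAnnotationSet:
    """Annotation sets with exactly one term planted to overlap the hit list.

    The planted term contains ``planted_overlap`` hit identifiers plus
    random non-hits; every other term is sampled uniformly from the
    background, so the planted overlap exceeds its null expectation.
    ``background`` and ``hit_list`` default to synthesised identifiers but
    may be supplied (e.g. real target symbols from an upstream screen).
    """
    if background is not None:
        background_size = len(background)
    if hit_list is not None:
        hit_list_size = len(hit_list)
    lo, hi = term_size_range
    if not (0 < lo <= hi <= background_size):
        raise ValueError("invalid term_size_range")
    if planted_overlap > hit_list_size:
        raise ValueError("planted_overlap cannot exceed hit_list_size")
    if planted_overlap > hi:
        raise ValueError("planted_overlap cannot exceed the maximum term size")
    rng = np.random.default_rng(seed)
    if background is None:
        background = [f"G{i + 1:04d}" for i in range(background_size)]
    else:
        background = sorted(str(x) for x in background)
    if hit_list is None:
        hits = list(rng.choice(background, size=hit_list_size, replace=False))
    else:
        hits = sorted(str(x) for x in hit_list)
        if not set(hits) <= set(background):
            raise ValueError("hit_list must be a subset of the background")
    non_hits = [g for g in background if g not in set(hits)]

    terms: dict[str, set[str]] = {}
    planted = "T0001"
    size = int(rng.integers(max(lo, planted_overlap), hi + 1))
    fill = list(rng.choice(non_hits, size=size - planted_overlap, replace=False))
    terms[planted] = set(rng.choice(hits, size=planted_overlap, replace=False)) | set(fill)
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"T{t + 1:04d}"] = set(rng.choice(background, size=size, replace=False))
    ann = AnnotationSets(set(background), terms, namespace="pathway")
    return SyntheticAnnotationSet(ann, planted, set(hits))


def gen_fit_score_table(
    compounds: list[str],
    true_targets: dict[str, set[str]],
    noise_targets_per_compound: int = 5,
    seed: int = 0,
) -> FitScoreTable:
    """Fit-score table whose planted pairs score in [4, 8] and noise pairs
    in [0, 3.4], so the ≥4.0 retention rule recovers the truth exactly."""
    if not compounds:
        raise ValueError("compound list is empty")
    rng = np.random.default_rng(seed)
    noise_pool = [f"NT{i + 1:04d}" for i in range(max(50, 2 * noise_targets_per_compound))]
    rows = []
    for c in compounds:
        truths = sorted(true_targets.get(c, set()))
        for t in truths:
            rows.append((c, t, float(np.round(rng.uniform(4.0, 8.0), 3))))
        candidates = [t for t in noise_pool if t.upper() not in {x.upper() for x in truths}]
        chosen = rng.choice(candidates, size=noise_targets_per_compound, replace=False)
        for t in chosen:
            rows.append((c, t, float(np.round(rng.uniform(0.0, 3.4), 3))))
    return FitScoreTable(pd.DataFrame(rows, columns=["compound_id", "target_id", "fit_score"]))
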