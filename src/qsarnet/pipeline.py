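"""End-to-end orchestration of the synthetic study.

Stages run in dependency order: synthetic data → descriptor pruning →
PCA-80 → classifier factorial (±GA) → applicability domain → fit-score
filtering → target intersection → PPI topology → key-node screen → term
enrichment. Every stage writes plain-text outputs under the run directory
and is recorded in a YAML manifest with SHA-256 digests, so identical
configuration and seeds reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import ALGORITHMS, PROPERTIES, ClassifierSpec
from .enrich import enrich_terms
from .evaluate import applicability_domain, factorial_evaluate, select_best_models, split_dataset
from .ga import GAConfig
from .io import (
    write_descriptor_csv,
    write_edge_tsv,
    write_gmt,
    write_labels_csv,
    write_yaml,
)
from .network import filter_fit_scores, intersect_targets, screen_key_nodes, topology_metrics
from .prep import DescriptorMatrix, pca_reduce, prune_descriptors
from .synthetic import (
    gen_annotation_sets,
    gen_descriptor_dataset,
    gen_fit_score_table,
    gen_ppi_graph,
)

STAGES = ("synthetic", "prep", "qsar", "ad", "targets", "network", "enrichment")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


DEFAULT_CONFIG: dict[str, Any] = {
    "run_label": "demo",
    "seed": 0,
    "synthetic": {
        "properties": list(PROPERTIES),
        "n_compounds": 60,
        "n_descriptors": 40,
        "n_informative": 3,
        "effect_size": 3.0,
        "class_balance": 0.5,
        "correlated_frac": 0.10,
        "constant_frac": 0.05,
        "network": {"n_nodes": 44, "generator": "erdos_renyi", "p": 0.15},
        "n_active_compounds": 8,
        "targets_per_compound": 4,
        "disease_target_frac": 0.7,
        "noise_targets_per_compound": 5,
        "annotation": {"n_terms": 15, "term_size_range": [4, 12], "planted_overlap": 3},
    },
    "prep": {"var_tol": 1e-8, "corr_max": 0.95, "pca_threshold": 0.80},
    "qsar": {
        "algorithms": list(ALGORITHMS),
        "knn_k": 5,
        "rf_trees": 60,
        "ebpt_epochs": 80,
        "plsda_components": 2,
    },
    "ga": {
        "population_size": 16,
        "generations": 8,
        "crossover_prob": 0.8,
        "mutation_prob": 0.02,
        "tournament_size": 3,
        "elitism": 1,
        "init_inclusion_prob": 0.2,
        "penalty_lambda": 0.01,
        "cv_folds": 3,
    },
    "eval": {"ratios": [0.6, 0.2, 0.2], "loo": False},
    "network": {"fit_threshold": 4.0, "fit_fallback": 3.5, "drop_isolated": True},
    "enrichment": {"method": "ease", "alpha": 0.05},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if k not in base:
            raise ConfigError(f"unknown config key {k!r}")
        out[k] = _merge(base[k], v) if isinstance(base[k], dict) and isinstance(v, dict) else v
    return out


def make_config(override: dict | None = None, seed: int | None = None) -> dict:
    """Full configuration: defaults overlaid with ``override``; every
    stochastic stage derives its seed from the top-level ``seed``."""
    cfg = _merge(DEFAULT_CONFIG, override or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


@dataclass
class RunManifest:
    """Ordered stage records plus the config snapshot."""

    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def record(self, name: str, status: str, outputs: list[Path], note: str = "") -> None:
        digests = {}
        for p in outputs:
            digests[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        self.stages.append(
            {"stage": name, "status": status, "outputs": [str(p) for p in outputs],
             "digests": digests, "note": note}
        )

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config, "stages": self.stages}


def _classifier_specs(cfg: dict, seed: int) -> dict[str, ClassifierSpec]:
    q = cfg["qsar"]
    hp = {
        "KNN": {"k": q["knn_k"]},
        "SVM": {},
        "RF": {"n_trees": q["rf_trees"]},
        "PLSDA": {"n_components": q["plsda_components"]},
        "EBPT": {"epochs": q["ebpt_epochs"]},
    }
    specs = {}
    for alg in cfg["qsar"]["algorithms"]:
        if alg not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {alg!r}")
        specs[alg] = ClassifierSpec(alg, hp[alg], seed=seed)
    return specs


def run_pipeline(cfg: dict, out_dir) -> RunManifest:
    """Execute all stages; on stage failure, dependents are skipped and the
    manifest records the failure (callers should exit non-zero)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    seed = int(cfg["seed"])
    state: dict[str, Any] = {}
    failed = False

    def stage(name, fn):
        nonlocal failed
        if failed:
            manifest.record(name, "skipped", [], note="upstream failure")
            return
        try:
            outputs = fn()
            manifest.record(name, "ok", outputs)
        except Exception as exc:  # noqa: BLE001 - manifest carries the failure
            warnings.warn(f"stage {name} failed: {exc}")
            manifest.record(name, "failed", [], note=f"{exc}\n{traceback.format_exc(limit=3)}")
            failed = True

    # ---------------------------------------------------------- synthetic
    def synthetic_stage() -> list[Path]:
        s = cfg["synthetic"]
        outputs = []
        qsar_sets = {}
        for i, prop in enumerate(s["properties"]):
            ds = gen_descriptor_dataset(
                s["n_compounds"], s["n_descriptors"], s["n_informative"],
                effect_size=s["effect_size"], class_balance=s["class_balance"],
                seed=seed + 101 * i, property=prop,
                correlated_frac=s["correlated_frac"], constant_frac=s["constant_frac"],
            )
            qsar_sets[prop] = ds
            mpath, lpath = out / f"descriptors_{prop}.csv", out / f"labels_{prop}.csv"
            write_descriptor_csv(ds.matrix, mpath)
            write_labels_csv(ds.labels, lpath)
            outputs += [mpath, lpath]
        state["qsar_sets"] = qsar_sets

        net = gen_ppi_graph(
            s["network"]["n_nodes"], s["network"]["generator"],
            {k: v for k, v in s["network"].items() if k not in ("n_nodes", "generator")},
            seed=seed + 7,
        )
        state["graph"] = net.graph
        gpath = out / "ppi_edges.tsv"
        write_edge_tsv(net.graph, gpath)
        outputs.append(gpath)

        rng = np.random.default_rng(seed + 11)
        nodes = sorted(net.graph.nodes())
        n_dis = max(1, int(round(s["disease_target_frac"] * len(nodes))))
        state["disease_targets"] = {str(t) for t in rng.choice(nodes, size=n_dis, replace=False)}
        compounds = [f"C{i + 1:04d}" for i in range(s["n_active_compounds"])]
        truth = {
            c: {str(t) for t in rng.choice(nodes, size=s["targets_per_compound"], replace=False)}
            for c in compounds
        }
        state["target_truth"] = truth
        fst = gen_fit_score_table(
            compounds, truth, s["noise_targets_per_compound"], seed=seed + 13
        )
        state["fit_scores"] = fst
        fpath = out / "fit_scores.tsv"
        fst.rows.to_csv(fpath, sep="\t", index=False)
        outputs.append(fpath)

        tpath = out / "truth.yaml"
        write_yaml(
            {
                "informative_descriptors": {p: d.informative_names for p, d in qsar_sets.items()},
                "disease_targets": sorted(state["disease_targets"]),
                "compound_targets": {c: sorted(t) for c, t in truth.items()},
            },
            tpath,
        )
        outputs.append(tpath)
        return outputs

    # --------------------------------------------------------------- prep
    def prep_stage() -> list[Path]:
        pr = cfg["prep"]
        outputs = []
        features = {}
        for prop, ds in state["qsar_sets"].items():
            # fit pruning and PCA on the training partition only; the same
            # seeded split is re-derived inside the factorial stage
            split = split_dataset(ds.matrix, ds.labels, tuple(cfg["eval"]["ratios"]), seed)
            trs = ds.matrix.rows(split.ids("TRS"))
            pruned_trs, report = prune_descriptors(trs, pr["var_tol"], pr["corr_max"])
            _, proj = pca_reduce(pruned_trs, pr["pca_threshold"])
            scores = proj.transform(ds.matrix.select(pruned_trs.descriptor_names))
            features[prop] = DescriptorMatrix(
                ds.matrix.compound_ids, proj.score_names(), scores
            )
            rpath = out / f"pruning_{prop}.tsv"
            report.to_frame().to_csv(rpath, sep="\t", index=False)
            ppath = out / f"pca_{prop}.yaml"
            write_yaml(
                {"n_retained": proj.n_retained,
                 "explained_variance_ratio": [float(v) for v in proj.explained_variance_ratio],
                 "descriptors": proj.descriptor_names},
                ppath,
            )
            outputs += [rpath, ppath]
        state["features"] = features
        return outputs

    # --------------------------------------------------------------- qsar
    def qsar_stage() -> list[Path]:
        specs = _classifier_specs(cfg, seed)
        ga_cfg = GAConfig(**cfg["ga"], seed=seed)
        datasets = {
            prop: (state["features"][prop], state["qsar_sets"][prop].labels)
            for prop in state["features"]
        }
        table = factorial_evaluate(
            datasets, specs, ga_cfg, tuple(cfg["eval"]["ratios"]), seed,
            loo=cfg["eval"]["loo"],
        )
        state["model_table"] = table
        tpath = out / "model_table.tsv"
        table.to_csv(tpath, sep="\t", index=False, float_format="%.6f")
        best = select_best_models(table)
        state["best_models"] = best
        bpath = out / "best_models.tsv"
        best.to_csv(bpath, sep="\t", index=False, float_format="%.6f")
        return [tpath, bpath]

    # ----------------------------------------------------------------- ad
    def ad_stage() -> list[Path]:
        outputs = []
        for prop, X in state["features"].items():
            labels = state["qsar_sets"][prop].labels
            split = split_dataset(X, labels, tuple(cfg["eval"]["ratios"]), seed)
            trs = X.rows(split.ids("TRS"))
            report = applicability_domain(trs, X)
            path = out / f"ad_{prop}.tsv"
            df = report.to_frame(X.compound_ids)
            df.insert(0, "h_star", report.h_star)
            df.to_csv(path, sep="\t", float_format="%.6f")
            outputs.append(path)
        return outputs

    # -------------------------------------------------------------- targets
    def targets_stage() -> list[Path]:
        ncfg = cfg["network"]
        retained = filter_fit_scores(
            state["fit_scores"], ncfg["fit_threshold"], ncfg["fit_fallback"]
        )
        compound_targets = set().union(*retained.values()) if retained else set()
        common, sizes = intersect_targets(compound_targets, state["disease_targets"])
        state["common_targets"] = common
        path = out / "common_targets.tsv"
        with open(path, "w") as fh:
            fh.write(f"# |compound_targets|={sizes[0]}\t|disease_targets|={sizes[1]}\t|overlap|={sizes[2]}\n")
            fh.write("target\n")
            for t in sorted(common):
                fh.write(t + "\n")
        return [path]

    # -------------------------------------------------------------- network
    def network_stage() -> list[Path]:
        sub = state["graph"].subgraph(state["common_targets"]).copy()
        topo = topology_metrics(sub, drop_isolated=cfg["network"]["drop_isolated"])
        state["topology"] = topo
        key = screen_key_nodes(topo)
        state["key_targets"] = key
        tpath = out / "topology.tsv"
        topo.per_node.sort_index().to_csv(tpath, sep="\t", float_format="%.6f")
        kpath = out / "key_targets.tsv"
        with open(kpath, "w") as fh:
            fh.write(f"# avg_DV={topo.mean_dv:.6f}\tavg_NBC={topo.mean_nbc:.6f}\tavg_NCC={topo.mean_ncc:.6f}\n")
            fh.write(f"# centralization={topo.centralization:.6f}\theterogeneity={topo.heterogeneity:.6f}\n")
            fh.write("target\n")
            for t in sorted(key.members):
                fh.write(t + "\n")
        return [tpath, kpath]

    # ----------------------------------------------------------- enrichment
    def enrichment_stage() -> list[Path]:
        e = cfg["enrichment"]
        a = cfg["synthetic"]["annotation"]
        hits = state["key_targets"].members or set(state["common_targets"])
        universe = sorted(state["graph"].nodes())
        ann_set = gen_annotation_sets(
            background_size=len(universe),
            n_terms=a["n_terms"],
            term_size_range=tuple(a["term_size_range"]),
            hit_list_size=max(len(hits), 1),
            planted_overlap=min(a["planted_overlap"], max(len(hits), 1)),
            seed=seed + 17,
            background=universe,
            hit_list=hits,
        )
        gpath = out / "annotation.gmt"
        write_gmt(ann_set.annotation, gpath)
        result = enrich_terms(hits, ann_set.annotation, method=e["method"], alpha=e["alpha"])
        state["enrichment"] = result
        rpath = out / "enrichment.tsv"
        result.table.to_csv(rpath, sep="\t", index=False, float_format="%.6g")
        return [gpath, rpath]

    stage("synthetic", synthetic_stage)
    stage("prep", prep_stage)
    stage("qsar", qsar_stage)
    stage("ad", ad_stage)
    stage("targets", targets_stage)
    stage("network", network_stage)
    stage("enrichment", enrichment_stage)

    mpath = out / "manifest.yaml"
    write_yaml(manifest.to_dict(), mpath)
    return manifest
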