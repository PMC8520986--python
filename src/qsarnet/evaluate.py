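"""Model evaluation: splits, cross-validation, the model factorial and
leverage-based applicability-domain analysis.

The factorial crosses every ADME property with every classifier, with and
without GA descriptor selection (5 × 5 × 2 = 50 models at full scale). Per
property the best model is the one with the highest validation-set (VAS)
accuracy; ties go to the model with fewer features, then to the documented
algorithm order, then to the GA-free variant.

The applicability domain is the leverage construction: with an intercept
column appended, h_i = x_i (XᵀX)⁻¹ x_iᵀ, warning leverage h* = 3(p+1)/n;
a query is out of domain when h > h*. Classification has no continuous
residual, so no residual axis is reported — a misclassification flag can be
joined externally where a Williams-style view is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import (
    ALGORITHMS,
    ClassifierSpec,
    PropertyLabels,
    train_classifier,
)
from .ga import GAConfig, run_ga
from .prep import DescriptorMatrix

PARTITIONS = ("TRS", "TES", "VAS")


@dataclass
class SplitAssignment:
    """Stratified three-way compound partition (training/test/validation)."""

    assignment: dict[str, str]  # compound_id -> TRS|TES|VAS
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return [c for c, p in self.assignment.items() if p == partition]

    def sizes(self) -> dict[str, int]:
        return {p: len(self.ids(p)) for p in PARTITIONS}


def _allocate(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n items over three ratios."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(v)) for v in raw]
    short = n - sum(base)
    order = np.argsort([b - v for b, v in zip(base, raw)])  # most-negative remainder first
    for i in range(short):
        base[order[i]] += 1
    return base


def split_dataset(
    X, y: PropertyLabels, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Seeded stratified split into TRS/TES/VAS.

    Stratification is per class with largest-remainder rounding, so class
    proportions in each partition match the full set within one compound.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    ids = list(y.compound_ids)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in ("+", "-"):
        members = [c for c, lab in zip(ids, y.classes) if lab == cls]
        rng.shuffle(members)
        counts = _allocate(len(members), ratios)
        if any(c == 0 for c in counts):
            raise ValueError(
                f"class {cls!r} has {len(members)} compounds; "
                f"cannot place at least one in every partition"
            )
        pos = 0
        for part, cnt in zip(PARTITIONS, counts):
            for c in members[pos : pos + cnt]:
                assignment[c] = part
            pos += cnt
    # keep original compound order in the mapping
    return SplitAssignment({c: assignment[c] for c in ids}, tuple(ratios), seed)


def _fold_accuracy(
    X: np.ndarray, y: PropertyLabels, spec: ClassifierSpec,
    train_idx: np.ndarray, test_idx: np.ndarray,
) -> int:
    """Correct-prediction count on one fold; degenerate single-class
    training folds fall back to predicting the training majority."""
    train_classes = [y.classes[i] for i in train_idx]
    if len(set(train_classes)) < 2 or min(
        train_classes.count("+"), train_classes.count("-")
    ) < 2:
        warnings.warn("degenerate training fold: predicting training majority class")
        majority = max(("-", "+"), key=train_classes.count)
        return sum(y.classes[i] == majority for i in test_idx)
    y_tr = PropertyLabels(
        [y.compound_ids[i] for i in train_idx], y.property, train_classes
    )
    model = train_classifier(X[train_idx], y_tr, spec)
    pred = model.predict(X[test_idx])
    return sum(p == y.classes[i] for p, i in zip(pred, test_idx))


def cross_validate(
    X, y: PropertyLabels, spec: ClassifierSpec,
    scheme: str = "kfold", k: int = 5, seed: int = 0,
) -> float:
    """Held-out accuracy under leave-one-out or stratified k-fold CV.

    ``scheme`` is ``"loo"`` or ``"kfold"``. LOO is deterministic; k-fold
    folds are stratified and shuffled from ``seed``. ``k == n`` reproduces
    the LOO fold structure exactly.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("feature rows and labels differ in length")
    if scheme == "loo" or (scheme == "kfold" and k == n):
        if n < 2:
            raise ValueError("LOO requires at least 2 compounds")
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        if not (2 <= k <= n):
            raise ValueError("need n >= k >= 2 for k-fold CV")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y.y))
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    correct = sum(_fold_accuracy(X, y, spec, tr, te) for tr, te in folds)
    return correct / n


#: ModelTable column order
MODEL_TABLE_COLUMNS = [
    "property", "algorithm", "ga_used", "n_features",
    "trs_accuracy", "tes_accuracy", "vas_accuracy",
    "loo_accuracy", "cv5_accuracy", "failed",
]


def _accuracy_on(model, X: np.ndarray, y: PropertyLabels) -> float:
    pred = model.predict(X)
    return float(np.mean([p == c for p, c in zip(pred, y.classes)]))


def factorial_evaluate(
    datasets: dict[str, tuple[DescriptorMatrix, PropertyLabels]],
    algorithms: dict[str, ClassifierSpec],
    ga_config: GAConfig | None = None,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    loo: bool = True,
    include_ga: bool = True,
) -> pd.DataFrame:
    """Evaluate every (property, algorithm, ±GA) combination.

    Returns one row per combination with TRS/TES/VAS accuracies plus LOO and
    5-fold CV accuracy on the training partition. A combination whose
    training fails is recorded with ``failed=True`` and NaN accuracies; the
    table is produced regardless. ``include_ga=False`` restricts the
    factorial to the GA-free variants.
    """
    if ga_config is None:
        ga_config = GAConfig()
    ga_variants = (False, True) if include_ga else (False,)
    rows = []
    for prop, (X, y) in datasets.items():
        split = split_dataset(X, y, ratios, seed)
        parts = {p: split.ids(p) for p in PARTITIONS}
        Xp = {p: X.rows(ids) for p, ids in parts.items()}
        yp = {p: y.subset(ids) for p, ids in parts.items()}
        for alg, spec in algorithms.items():
            for ga_used in ga_variants:
                row = {
                    "property": prop, "algorithm": alg, "ga_used": ga_used,
                    "n_features": np.nan, "trs_accuracy": np.nan,
                    "tes_accuracy": np.nan, "vas_accuracy": np.nan,
                    "loo_accuracy": np.nan, "cv5_accuracy": np.nan,
                    "failed": False,
                }
                try:
                    if ga_used:
                        run = run_ga(
                            Xp["TRS"], yp["TRS"], spec, ga_config,
                            feature_names=list(X.descriptor_names),
                        )
                        names = run.selected_names
                    else:
                        names = list(X.descriptor_names)
                    Xsel = {p: Xp[p].select(names) for p in PARTITIONS}
                    model = train_classifier(Xsel["TRS"], yp["TRS"], spec)
                    row["n_features"] = len(names)
                    for p, key in (("TRS", "trs_accuracy"), ("TES", "tes_accuracy"),
                                   ("VAS", "vas_accuracy")):
                        row[key] = _accuracy_on(model, Xsel[p].values, yp[p])
                    if loo:
                        row["loo_accuracy"] = cross_validate(
                            Xsel["TRS"], yp["TRS"], spec, scheme="loo"
                        )
                    row["cv5_accuracy"] = cross_validate(
                        Xsel["TRS"], yp["TRS"], spec, scheme="kfold", k=5, seed=seed
                    )
                except Exception as exc:  # noqa: BLE001 - row-level failure is data
                    warnings.warn(f"{prop}/{alg}/ga={ga_used} failed: {exc}")
                    row["failed"] = True
                rows.append(row)
    return pd.DataFrame(rows, columns=MODEL_TABLE_COLUMNS)


def select_best_models(table: pd.DataFrame) -> pd.DataFrame:
    """Per property, the row with the highest VAS accuracy.

    Ties break to fewer features, then algorithm order
    (KNN, SVM, RF, PLSDA, EBPT), then the GA-free variant.
    """
    alg_rank = {a: i for i, a in enumerate(ALGORITHMS)}
    best_rows = []
    for prop, grp in table[~table["failed"]].groupby("property", sort=False):
        key = grp.apply(
            lambda r: (-r["vas_accuracy"], r["n_features"],
                       alg_rank[r["algorithm"]], bool(r["ga_used"])),
            axis=1,
        )
        best_rows.append(grp.loc[key.sort_values(kind="stable").index[0]])
    return pd.DataFrame(best_rows).reset_index(drop=True)


@dataclass
class ADReport:
    """Leverage-based applicability-domain report."""

    leverages: np.ndarray          # per query compound
    train_leverages: np.ndarray    # per training compound
    h_star: float
    in_domain: np.ndarray          # per query compound, h <= h*
    n_train: int
    p_features: int

    def to_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"leverage": self.leverages, "in_domain": self.in_domain})
        if ids is not None:
            df.index = ids
        df.attrs["h_star"] = self.h_star
        return df


def applicability_domain(X_train, X_query=None) -> ADReport:
    """Leverage of query compounds relative to a training descriptor matrix.

    An intercept column is appended, so h_i = a_i (AᵀA)⁻¹ a_iᵀ with
    a_i = (1, x_i); training leverages sum to p+1 and the warning leverage
    is h* = 3(p+1)/n. With no query, the training compounds are assessed.
    """
    Xt = np.asarray(getattr(X_train, "values", X_train), dtype=float)
    n, p = Xt.shape
    if n <= p + 1:
        raise ValueError("need n_train > p_features + 1 for a well-posed hat matrix")
    A = np.column_stack([np.ones(n), Xt])
    AtA = A.T @ A
    if np.linalg.cond(AtA) > 1e12:
        raise np.linalg.LinAlgError(
            "XᵀX is (near-)singular; prune correlated descriptors or use PCA scores first"
        )
    G = np.linalg.inv(AtA)
    train_h = np.einsum("ij,jk,ik->i", A, G, A)
    if X_query is None:
        query_h = train_h
    else:
        Xq = np.asarray(getattr(X_query, "values", X_query), dtype=float)
        if Xq.ndim != 2 or Xq.shape[1] != p:
            raise ValueError(f"query must have {p} feature columns")
        Q = np.column_stack([np.ones(Xq.shape[0]), Xq])
        query_h = np.einsum("ij,jk,ik->i", Q, G, Q)
    h_star = 3.0 * (p + 1) / n
    return ADReport(
        leverages=query_h,
        train_leverages=train_h,
        h_star=h_star,
        in_domain=query_h <= h_star,
        n_train=n,
        p_features=p,
    )
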