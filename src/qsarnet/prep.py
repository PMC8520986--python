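"""Descriptor-matrix pretreatment.

QSAR feature spaces built from 1D/2D molecular descriptors are heavily
redundant: many descriptors are (near-)constant over a compound set and many
pairs are collinear by construction. Pretreatment here follows standard QSAR
practice — drop low-variance and highly correlated columns, z-score the
survivors, and reduce to the leading principal components that reach a
cumulative explained-variance threshold (the "PCA-80" feature space at the
default threshold of 0.80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class EmptyFeatureSpaceError(ValueError):
    """Raised when pruning removes every descriptor column."""


@dataclass
class DescriptorMatrix:
    """Compound × descriptor numeric table (unitless descriptor values).

    Parameters
    ----------
    compound_ids : list of str
        Ordered, unique compound identifiers (rows).
    descriptor_names : list of str
        Ordered, unique descriptor identifiers (columns).
    values : ndarray of shape (n_compounds, n_descriptors)
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds × {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound identifiers")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select(self, names: list[str]) -> "DescriptorMatrix":
        """Column-subset by descriptor name, preserving this matrix's order."""
        wanted = set(names)
        keep = [j for j, n in enumerate(self.descriptor_names) if n in wanted]
        missing = wanted - set(self.descriptor_names)
        if missing:
            raise KeyError(f"unknown descriptors: {sorted(missing)}")
        return DescriptorMatrix(
            self.compound_ids,
            [self.descriptor_names[j] for j in keep],
            self.values[:, keep],
        )

    def rows(self, ids: list[str]) -> "DescriptorMatrix":
        """Row-subset by compound id, in the requested order."""
        index = {c: i for i, c in enumerate(self.compound_ids)}
        idx = [index[c] for c in ids]
        return DescriptorMatrix(list(ids), self.descriptor_names, self.values[idx])


@dataclass
class PruningReport:
    """Record of removed descriptors with the single reason per removal."""

    removed: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)
    var_tol: float = 1e-8
    corr_max: float = 0.95
    imputed: list[str] = field(default_factory=list)

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["descriptor", "reason"])


@dataclass
class PCAProjection:
    """Fitted standardize-then-PCA transform, reusable on held-out compounds."""

    component_loadings: np.ndarray  # (n_retained, p)
    explained_variance_ratio: np.ndarray  # all components, non-increasing
    n_retained: int
    center: np.ndarray
    scale: np.ndarray
    descriptor_names: list[str]
    cum_var_threshold: float

    def transform(self, X: DescriptorMatrix) -> np.ndarray:
        if list(X.descriptor_names) != list(self.descriptor_names):
            raise ValueError("descriptor names do not match the fitted projection")
        Z = (X.values - self.center) / self.scale
        return Z @ self.component_loadings.T

    def score_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_retained)]


def clean_nonfinite(
    X: DescriptorMatrix, max_nonfinite_frac: float = 0.20
) -> tuple[DescriptorMatrix, list[str], list[str]]:
    """Handle non-finite descriptor cells.

    Columns with more than ``max_nonfinite_frac`` non-finite entries are
    dropped; remaining non-finite cells are imputed with the column median.
    Returns (cleaned matrix, dropped names, imputed names).
    """
    vals = X.values.copy()
    finite = np.isfinite(vals)
    frac_bad = 1.0 - finite.mean(axis=0)
    drop = frac_bad > max_nonfinite_frac
    imputed: list[str] = []
    for j in np.flatnonzero(~drop):
        col_bad = ~finite[:, j]
        if col_bad.any():
            med = np.median(vals[finite[:, j], j]) if finite[:, j].any() else 0.0
            vals[col_bad, j] = med
            imputed.append(X.descriptor_names[j])
    keep = np.flatnonzero(~drop)
    cleaned = DescriptorMatrix(
        X.compound_ids, [X.descriptor_names[j] for j in keep], vals[:, keep]
    )
    dropped = [X.descriptor_names[j] for j in np.flatnonzero(drop)]
    return cleaned, dropped, imputed


def prune_descriptors(
    X: DescriptorMatrix,
    var_tol: float = 1e-8,
    corr_max: float = 0.95,
    max_nonfinite_frac: float = 0.20,
) -> tuple[DescriptorMatrix, PruningReport]:
    """Remove non-finite, low-variance and highly correlated descriptors.

    The correlation pass is a deterministic greedy scan in column order: a
    column is removed when its absolute Pearson correlation with an earlier
    retained column exceeds ``corr_max`` (the later column loses).

    Raises
    ------
    EmptyFeatureSpaceError
        If no descriptor survives.
    """
    if X.shape[1] == 0:
        raise EmptyFeatureSpaceError("input matrix has no descriptor columns")
    if not (0.0 < corr_max <= 1.0):
        raise ValueError("corr_max must be in (0, 1]")
    if var_tol < 0:
        raise ValueError("var_tol must be non-negative")

    report = PruningReport(var_tol=var_tol, corr_max=corr_max)
    cleaned, dropped_nf, imputed = clean_nonfinite(X, max_nonfinite_frac)
    report.removed.extend((n, "non_finite") for n in dropped_nf)
    report.imputed = imputed
    if imputed:
        warnings.warn(f"imputed {len(imputed)} descriptor column(s) with the column median")

    vals = cleaned.values
    variances = vals.var(axis=0)  # population variance; threshold is near-zero anyway
    low_var = variances <= var_tol
    report.removed.extend(
        (cleaned.descriptor_names[j], "low_variance") for j in np.flatnonzero(low_var)
    )
    keep_idx = np.flatnonzero(~low_var)
    if keep_idx.size == 0:
        raise EmptyFeatureSpaceError("all descriptors removed by the variance filter")

    sub = vals[:, keep_idx]
    # centred/normalised columns -> correlation = dot product
    Z = sub - sub.mean(axis=0)
    norms = np.linalg.norm(Z, axis=0)
    Z = Z / norms
    corr = np.clip(Z.T @ Z, -1.0, 1.0)

    retained: list[int] = []
    for local_j in range(len(keep_idx)):
        name = cleaned.descriptor_names[keep_idx[local_j]]
        if any(abs(corr[local_j, i]) > corr_max for i in retained):
            report.removed.append((name, "high_correlation"))
        else:
            retained.append(local_j)
    if not retained:
        raise EmptyFeatureSpaceError("all descriptors removed")

    final_idx = keep_idx[retained]
    pruned = DescriptorMatrix(
        cleaned.compound_ids,
        [cleaned.descriptor_names[j] for j in final_idx],
        vals[:, final_idx],
    )
    return pruned, report


def pca_reduce(
    X: DescriptorMatrix, cum_var_threshold: float = 0.80
) -> tuple[np.ndarray, PCAProjection]:
    """Standardize columns and project onto leading principal components.

    ``n_retained`` is the smallest m whose cumulative explained-variance
    ratio reaches ``cum_var_threshold``. Returns the training score matrix
    and the fitted projection (center/scale/loadings) for held-out use.
    """
    if not (0.0 < cum_var_threshold <= 1.0):
        raise ValueError("cum_var_threshold must be in (0, 1]")
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 compounds")
    center = X.values.mean(axis=0)
    scale = X.values.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("constant column present; prune before PCA")
    Z = (X.values - center) / scale
    pca = PCA(svd_solver="full")
    scores_all = pca.fit_transform(Z)
    ratio = pca.explained_variance_ratio_
    nonzero = pca.explained_variance_ > 1e-12
    cum = np.cumsum(ratio)
    if cum_var_threshold >= 1.0:
        n_retained = int(nonzero.sum())
    else:
        n_retained = int(np.searchsorted(cum, cum_var_threshold - 1e-12) + 1)
        n_retained = min(n_retained, len(ratio))
    proj = PCAProjection(
        component_loadings=pca.components_[:n_retained],
        explained_variance_ratio=ratio,
        n_retained=n_retained,
        center=center,
        scale=scale,
        descriptor_names=list(X.descriptor_names),
        cum_var_threshold=cum_var_threshold,
    )
    return scores_all[:, :n_retained], proj
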