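"""Local over-representation analysis for annotation term sets.

For a hit list of n identifiers drawn from a background of N, and a term
annotating K of the N, the overlap k is scored by:

* fold enrichment  = (k/n) / (K/N)
* Fisher p         = one-tailed hypergeometric upper tail P(X ≥ k)
* EASE p           = same tail with the overlap cell replaced by
  max(k − 1, 0) while the margins (K, n, N) are unchanged — the
  conservative "improved Fisher exact" convention of DAVID.

Raw p-values are corrected with Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationSets:
    """Background identifiers and term → member-set annotations."""

    background: set[str]
    terms: dict[str, set[str]]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        self.background = {str(x) for x in self.background}
        self.terms = {str(t): {str(x) for x in members} for t, members in self.terms.items()}
        for t, members in self.terms.items():
            extra = members - self.background
            if extra:
                raise ValueError(f"term {t!r} has members outside the background: {sorted(extra)[:5]}")


def fisher_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE score: Fisher tail with the overlap reduced by one."""
    return fisher_tail_p(max(k - 1, 0), K, n, N)


def adjust_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and ``q < alpha`` flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics, sorted by raw p."""

    table: pd.DataFrame  # term, k, K, n, N, fold_enrichment, p_raw, q_bh, significant
    method: str
    alpha: float
    dropped_hits: int = 0
    warnings_: list[str] = field(default_factory=list)

    def significant_terms(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "term"])


def enrich_terms(
    hit_list: set[str],
    ann: AnnotationSets,
    method: str = "fisher",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Score every annotation term against a hit list.

    Hits outside the background are dropped with a warning count. Results
    are sorted by raw p (ties by term id) and BH-adjusted across all terms.
    """
    if method not in ("fisher", "ease"):
        raise ValueError("method must be 'fisher' or 'ease'")
    if not ann.background:
        raise ValueError("background is empty")
    hits = {str(x) for x in hit_list}
    dropped = hits - ann.background
    if dropped:
        warnings.warn(f"dropped {len(dropped)} hit(s) outside the background")
    hits &= ann.background
    if not hits:
        raise ValueError("hit list is empty after background filtering")

    N, n = len(ann.background), len(hits)
    pfun = fisher_tail_p if method == "fisher" else ease_p
    rows = []
    for term, members in ann.terms.items():
        K = len(members)
        k = len(members & hits)
        fold = (k / n) / (K / N) if K > 0 else np.nan
        rows.append({
            "term": term, "k": k, "K": K, "n": n, "N": N,
            "fold_enrichment": fold,
            "p_raw": pfun(k, K, n, N) if k > 0 else 1.0,
        })
    df = pd.DataFrame(rows).sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
    q, sig = adjust_bh(df["p_raw"].to_numpy(), alpha)
    df["q_bh"] = q
    df["significant"] = sig
    df["method"] = method
    return EnrichmentResult(table=df, method=method, alpha=alpha, dropped_hits=len(dropped))
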