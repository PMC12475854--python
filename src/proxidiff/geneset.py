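"""Over-representation analysis of a hit list against user-supplied gene sets.

For each term the hit list is tested against an explicit background universe
with the one-sided (upper tail) hypergeometric test; p-values are adjusted by
Benjamini-Hochberg across all tested terms, and the effect size is reported
as fold enrichment: (k/n) / (K/N), the fraction of hit genes in the term
divided by the corresponding background fraction.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix_io import GeneSetCollection

__all__ = [
    "hypergeom_overrep",
    "fold_enrichment",
    "bh_fdr",
    "run_overrepresentation",
]


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")


def hypergeom_overrep(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term members among n draws without replacement from a universe
    of N genes of which K belong to the term.  k = 0 gives exactly 1.
    """
    _check_counts(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); NaN when the ratio is undefined (n == 0 or K == 0)."""
    if n == 0 or K == 0:
        return float("nan")
    _check_counts(k, n, K, N)
    return (k / n) / (K / N)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_overrepresentation(
    hits: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Test every term of a collection for over-representation in the hits.

    Hits outside the background are dropped with a warning; term membership
    is intersected with the background before counting.  Terms with no
    background member (K = 0) are not tested.  BH adjustment runs across all
    tested terms; the result is sorted by p (ties by term name).
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    hit_set = set(hits)
    outside = hit_set - bg
    if outside:
        warnings.warn(
            f"{len(outside)} hit gene(s) absent from the background were dropped",
            UserWarning,
            stacklevel=2,
        )
        hit_set &= bg

    N = len(bg)
    n = len(hit_set)
    rows = []
    for name, (desc, members) in collection:
        K_set = members & bg
        K = len(K_set)
        if K == 0:
            continue
        k = len(hit_set & K_set)
        rows.append(
            {
                "term": name,
                "description": desc,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold_enrichment(k, n, K, N),
                "p_hyper": hypergeom_overrep(k, n, K, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "description", "k", "n", "K", "N", "fold_enrichment", "p_hyper"]
    )
    if len(result):
        result["fdr_bh"] = bh_fdr(result["p_hyper"].to_numpy())
        result["significant"] = result["fdr_bh"] < fdr_cutoff
        result = result.sort_values(["p_hyper", "term"], kind="mergesort").reset_index(drop=True)
    else:
        result["fdr_bh"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
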