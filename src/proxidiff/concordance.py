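"""Gene-level concordance between two enrichment hit lists.

Two interactome datasets (e.g. a cell-culture and an in vivo run) are
compared on collapsed gene symbols of their hit rows: protein-group isoforms
of the same gene count as one entry, and symbols are case-normalized by
default because datasets from different species conventions mix
capitalizations (Bin1 vs BIN1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .matrix_io import collapse_to_genes

__all__ = ["ConcordanceResult", "gene_level_overlap", "write_concordance"]


@dataclass
class ConcordanceResult:
    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def _hit_genes(table: pd.DataFrame, normalize_case: bool) -> set[str]:
    hits = table[table["hit"].astype(bool)]
    genes, _ = collapse_to_genes(
        hits["protein_id"].astype(str).tolist(), hits["gene"].astype(str).tolist()
    )
    if normalize_case:
        genes = {g.strip().upper() for g in genes}
    return genes


def gene_level_overlap(
    hits_a: pd.DataFrame, hits_b: pd.DataFrame, normalize_case: bool = True
) -> ConcordanceResult:
    """Shared / unique gene sets between the hit rows of two enrichment tables."""
    a = _hit_genes(hits_a, normalize_case)
    b = _hit_genes(hits_b, normalize_case)
    return ConcordanceResult(
        shared=frozenset(a & b), unique_a=frozenset(a - b), unique_b=frozenset(b - a)
    )


def write_concordance(result: ConcordanceResult, path: str | Path) -> None:
    """Three-section TSV (shared / unique_a / unique_b) plus counts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("section\tgene\n")
        for section, genes in (
            ("shared", result.shared),
            ("unique_a", result.unique_a),
            ("unique_b", result.unique_b),
        ):
            for g in sorted(genes):
                fh.write(f"{section}\t{g}\n")
        fh.write(
            f"# counts\tshared={result.n_shared}\tunique_a={result.n_unique_a}"
            f"\tunique_b={result.n_unique_b}\n"
        )
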