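"""Reading and writing protein-group intensity matrices, designs, and gene sets.

The on-disk dialect is the wide tab-separated protein-group matrix produced
by DIA search engines (one row per protein group, leading annotation columns,
then one intensity column per sample/run).  Missing values may be encoded as
blank cells, textual codes ("NA", "NaN") or literal zeros; all are mapped to
an explicit missing state (NaN) on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "GroupDesign",
    "GeneSetCollection",
    "MatrixFormatError",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_design",
    "read_gmt",
    "collapse_to_genes",
    "write_enrichment_table",
    "read_enrichment_table",
    "ENRICHMENT_COLUMNS",
]


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


#: Missing-value tokens recognized by default (DIA-NN / Perseus exports).
DEFAULT_MISSING_CODES = frozenset({"", "NA", "NaN", "nan", "NAN", "#N/A", "NULL", "Filtered"})

#: Leading annotation columns of the DIA-NN pg_matrix dialect (case/sep-insensitive).
DEFAULT_ANNOTATION_COLUMNS = (
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
    "Description",
    "Majority protein IDs",
    "Protein IDs",
    "Gene names",
)

_GENE_COLUMN_KEYS = {"genes", "gene names"}


def _norm_colname(name: str) -> str:
    return name.strip().lower().replace(".", " ").replace("_", " ")


@dataclass
class IntensityMatrix:
    """Protein groups x samples intensity grid with explicit missingness.

    ``intensities`` is a float DataFrame indexed by unique protein-group ids
    with unique sample columns; NaN marks a missing (not-quantified) cell.
    ``genes`` holds one gene symbol per protein group ("" when unknown) and is
    aligned with the intensity index.  ``log2_scale`` records whether values
    are raw-scale (must be > 0) or already log2 transformed.
    """

    intensities: pd.DataFrame
    genes: pd.Series
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate protein-group identifier: {dup!r}")
        if not self.intensities.columns.is_unique:
            dup = self.intensities.columns[self.intensities.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample name: {dup!r}")
        self.intensities = self.intensities.astype(float)
        self.genes = self.genes.reindex(self.intensities.index).fillna("").astype(str)
        vals = self.intensities.to_numpy()
        present = ~np.isnan(vals)
        if np.isinf(vals[present]).any():
            raise MatrixFormatError("non-finite intensity value present")
        if not self.log2_scale and present.any() and (vals[present] <= 0).any():
            raise MatrixFormatError("raw-scale intensities must be strictly positive")

    # -- convenience ------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def subset(self, protein_ids: Iterable[str]) -> "IntensityMatrix":
        idx = pd.Index(protein_ids)
        return IntensityMatrix(
            self.intensities.loc[idx].copy(), self.genes.loc[idx].copy(), self.log2_scale
        )


@dataclass
class GroupDesign:
    """Sample -> group assignment for a two-group (bait vs control) comparison."""

    assignments: dict[str, str]
    bait_group: str
    control_group: str

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels != {self.bait_group, self.control_group}:
            raise ValueError(
                f"design labels {sorted(labels)} must be exactly "
                f"{{{self.bait_group!r}, {self.control_group!r}}}"
            )
        if self.bait_group == self.control_group:
            raise ValueError("bait and control groups must differ")
        for g in (self.bait_group, self.control_group):
            if len(self.samples_for(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    def samples_for(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def bait_samples(self) -> list[str]:
        return self.samples_for(self.bait_group)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_for(self.control_group)

    def validate_against(self, matrix: IntensityMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/SynGO-style terms) supplied by the user."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {name!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())


# ---------------------------------------------------------------------------
# protein matrix


def read_protein_matrix(
    path: str | Path,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    zero_is_missing: bool = True,
    annotation_columns: Iterable[str] | None = None,
) -> IntensityMatrix:
    """Read a wide TSV protein-group matrix into an :class:`IntensityMatrix`.

    Leading columns whose names match ``annotation_columns`` (by default the
    DIA-NN pg_matrix header) are treated as annotation; the first one supplies
    the protein-group identifier and a "Genes"-like one the gene symbols.
    Everything after the annotation block is a sample column.
    """
    path = Path(path)
    missing = {str(c) for c in missing_codes}
    ann_keys = [_norm_colname(c) for c in (annotation_columns or DEFAULT_ANNOTATION_COLUMNS)]

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise MatrixFormatError(f"duplicate sample name: {name!r}")
        seen.add(name)

    n_ann = 0
    for name in header:
        if _norm_colname(name) in ann_keys:
            n_ann += 1
        else:
            break
    if n_ann == 0:
        raise MatrixFormatError(
            f"no annotation columns recognized in header {header[:3]}...; "
            "pass annotation_columns= to name them"
        )
    if n_ann == len(header):
        raise MatrixFormatError("header contains annotation columns only, no samples")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ann_cols = list(raw.columns[:n_ann])
    sample_cols = list(raw.columns[n_ann:])

    protein_ids = raw[ann_cols[0]].str.strip()
    dup = protein_ids[protein_ids.duplicated()]
    if len(dup):
        raise MatrixFormatError(f"duplicate protein-group identifier: {dup.iloc[0]!r}")

    gene_col = next((c for c in ann_cols if _norm_colname(c) in _GENE_COLUMN_KEYS), None)
    genes = raw[gene_col].str.strip() if gene_col else pd.Series("", index=raw.index)

    values = np.full((len(raw), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        for i, token in enumerate(raw[col]):
            token = token.strip()
            if token in missing:
                continue
            try:
                v = float(token)
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric token {token!r} at row {i + 2}, column {col!r}"
                ) from None
            if zero_is_missing and v == 0.0:
                continue
            values[i, j] = v

    frame = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"), columns=sample_cols)
    return IntensityMatrix(frame, pd.Series(genes.values, index=frame.index))


def write_protein_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix in the same wide TSV dialect (missing cells left blank).

    Values are written with Python's shortest-roundtrip float repr, so
    reading the file back reproduces the matrix exactly.
    """
    out = pd.DataFrame(index=matrix.intensities.index)
    out.insert(0, "Protein.Group", matrix.intensities.index)
    out.insert(1, "Genes", matrix.genes.values)
    for col in matrix.intensities.columns:
        out[col] = [("" if np.isnan(v) else repr(v)) for v in matrix.intensities[col]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design table


def read_design(
    path: str | Path, bait_group: str, control_group: str | None = None
) -> GroupDesign:
    """Read a two-column TSV (sample_id, group) into a :class:`GroupDesign`.

    A header line is tolerated when its first field starts with "sample".
    """
    assignments: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MatrixFormatError(f"design line {lineno} has fewer than 2 fields")
            sample, group = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sample.lower().startswith("sample"):
                continue
            if sample in assignments:
                raise MatrixFormatError(f"duplicate sample {sample!r} in design")
            assignments[sample] = group
    labels = sorted(set(assignments.values()))
    if control_group is None:
        others = [g for g in labels if g != bait_group]
        if len(others) != 1:
            raise MatrixFormatError(
                f"cannot infer control group from labels {labels}; pass control_group"
            )
        control_group = others[0]
    return GroupDesign(assignments, bait_group, control_group)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member TAB member..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixFormatError(f"GMT line {lineno} has fewer than 3 fields")
            name, desc = parts[0].strip(), parts[1].strip()
            if name in terms:
                raise MatrixFormatError(f"duplicate term name {name!r} in GMT")
            members = frozenset(m.strip() for m in parts[2:] if m.strip())
            if not members:
                raise MatrixFormatError(f"GMT line {lineno} ({name!r}) has no members")
            terms[name] = (desc, members)
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# gene collapsing


def collapse_to_genes(
    protein_ids: Iterable[str],
    gene_symbols: Iterable[str],
    selector: Callable[[list[str]], str] | None = None,
) -> tuple[set[str], dict[str, list[str]]]:
    """Collapse protein-group rows (isoforms) to one entry per gene symbol.

    Rows with an empty symbol fall back to their protein id, so no row
    silently disappears.  Returns the collapsed gene set plus a mapping from
    each gene entry to the rows that fed it.  ``selector`` (per-gene tie rule)
    may pick a representative row per gene; it does not change the set.
    """
    pids = list(protein_ids)
    syms = list(gene_symbols)
    if len(pids) != len(syms):
        raise ValueError("protein_ids and gene_symbols must have equal length")
    mapping: dict[str, list[str]] = {}
    for pid, sym in zip(pids, syms):
        key = sym.strip() if sym and sym.strip() else pid
        mapping.setdefault(key, []).append(pid)
    if selector is not None:
        mapping = {g: [selector(rows)] for g, rows in mapping.items()}
    return set(mapping), mapping


# ---------------------------------------------------------------------------
# enrichment table I/O

ENRICHMENT_COLUMNS = [
    "protein_id",
    "gene",
    "n_valid_bait",
    "n_valid_ctrl",
    "diff_log2",
    "ratio",
    "p_welch",
    "z",
    "cv_bait_pct",
    "hit",
]

_EXTRA_COLUMNS = ["t_stat", "df_welch", "passed_filter", "passed_p", "passed_z"]
_INT_COLUMNS = {"n_valid_bait", "n_valid_ctrl"}
_BOOL_COLUMNS = {"hit", "passed_filter", "passed_p", "passed_z"}


def write_enrichment_table(
    table: pd.DataFrame, path: str | Path, include_extra: bool = False
) -> None:
    """Write an enrichment table as TSV (12-significant-digit floats).

    The fixed column set is written first; with ``include_extra`` the
    t statistic, Welch df and individual cutoff flags follow.
    """
    cols = list(ENRICHMENT_COLUMNS)
    if include_extra:
        cols += [c for c in _EXTRA_COLUMNS if c in table.columns]
    missing = [c for c in ENRICHMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"enrichment table missing columns: {missing}")
    out = table[cols].copy()
    for c in cols:
        if c in _BOOL_COLUMNS:
            out[c] = out[c].astype(bool)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for c in _BOOL_COLUMNS & set(table.columns):
        table[c] = table[c].astype(str).str.lower().isin({"true", "1"})
    for c in _INT_COLUMNS & set(table.columns):
        table[c] = table[c].astype(int)
    if "gene" in table.columns:
        table["gene"] = table["gene"].fillna("").astype(str)
    return table
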