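"""Matrix, design, GMT and enrichment-table I/O contracts."""

import numpy as np
import pandas as pd
import pytest

from proxidiff.matrix_io import (
    MatrixFormatError,
    collapse_to_genes,
    read_design,
    read_enrichment_table,
    read_gmt,
    read_protein_matrix,
    write_enrichment_table,
    write_protein_matrix,
)
from proxidiff.pipeline import PipelineParams, run_enrichment_pipeline
from proxidiff.synthetic import SimulationParams, default_design, simulate_lfq


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "Protein.Group\tGenes\ts1\ts2\ts3\n"


class TestReadProteinMatrix:
    def test_full_matrix_reads_identically(self, tmp_path):
        p = _write(tmp_path, HEADER + "P1\tBin1\t1.5\t2\t3\nP2\tAmph\t4\t5\t6.25\n")
        m = read_protein_matrix(p)
        assert m.protein_ids == ["P1", "P2"]
        assert m.sample_ids == ["s1", "s2", "s3"]
        assert m.genes.tolist() == ["Bin1", "Amph"]
        assert not m.missing_mask.to_numpy().any()
        assert m.intensities.loc["P2", "s3"] == 6.25

    @pytest.mark.parametrize("token", ["", "NA", "NaN", "0"])
    def test_missing_encodings(self, tmp_path, token):
        p = _write(tmp_path, HEADER + f"P1\tBin1\t{token}\t2\t3\n")
        m = read_protein_matrix(p, zero_is_missing=True)
        assert m.missing_mask.loc["P1", "s1"]
        assert m.missing_mask.to_numpy().sum() == 1

    def test_zero_kept_when_not_flagged(self, tmp_path):
        # a zero that is a real value violates the positivity invariant
        p = _write(tmp_path, HEADER + "P1\tBin1\t0\t2\t3\n")
        with pytest.raises(MatrixFormatError, match="positive"):
            read_protein_matrix(p, zero_is_missing=False)

    def test_duplicate_protein_id_named_in_error(self, tmp_path):
        p = _write(tmp_path, HEADER + "P1\tA\t1\t2\t3\nP1\tB\t4\t5\t6\n")
        with pytest.raises(MatrixFormatError, match="P1"):
            read_protein_matrix(p)

    def test_duplicate_sample_name_rejected(self, tmp_path):
        p = _write(tmp_path, "Protein.Group\tGenes\ts1\ts1\nP1\tA\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="s1"):
            read_protein_matrix(p)

    def test_non_numeric_token_reports_position(self, tmp_path):
        p = _write(tmp_path, HEADER + "P1\tA\t1\toops\t3\n")
        with pytest.raises(MatrixFormatError, match="row 2.*'s2'"):
            read_protein_matrix(p)

    def test_roundtrip_identity(self, tmp_path):
        matrix, _ = simulate_lfq(SimulationParams(n_proteins=40), seed=7)
        path = tmp_path / "sim.tsv"
        write_protein_matrix(matrix, path)
        back = read_protein_matrix(path)
        assert back.protein_ids == matrix.protein_ids
        assert back.sample_ids == matrix.sample_ids
        assert back.genes.tolist() == matrix.genes.tolist()
        pd.testing.assert_frame_equal(back.intensities, matrix.intensities)


class TestDesign:
    def test_read_and_infer_control(self, tmp_path):
        p = _write(
            tmp_path,
            "sample_id\tgroup\nb1\tbait\nb2\tbait\nc1\tcyto\nc2\tcyto\n",
            "d.tsv",
        )
        d = read_design(p, bait_group="bait")
        assert d.control_group == "cyto"
        assert sorted(d.bait_samples) == ["b1", "b2"]

    def test_more_than_two_groups_rejected(self, tmp_path):
        p = _write(tmp_path, "b1\tbait\nb2\tbait\nc1\tcyto\nx1\tother\n", "d.tsv")
        with pytest.raises(MatrixFormatError, match="infer"):
            read_design(p, bait_group="bait")

    def test_single_replicate_group_rejected(self, tmp_path):
        p = _write(tmp_path, "b1\tbait\nc1\tcyto\nc2\tcyto\n", "d.tsv")
        with pytest.raises(ValueError, match="fewer than 2"):
            read_design(p, bait_group="bait")


class TestGmt:
    def test_members_deduplicated(self, tmp_path):
        p = _write(tmp_path, "T1\tdesc\tA\tB\tA\n", "sets.gmt")
        coll = read_gmt(p)
        assert coll.terms["T1"][1] == frozenset({"A", "B"})

    def test_duplicate_term_rejected(self, tmp_path):
        p = _write(tmp_path, "T1\td\tA\nT1\td\tB\n", "sets.gmt")
        with pytest.raises(MatrixFormatError, match="T1"):
            read_gmt(p)

    def test_short_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "T1\td\tA\nT2\tonlydesc\n", "sets.gmt")
        with pytest.raises(MatrixFormatError, match="line 2"):
            read_gmt(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert len(read_gmt(_write(tmp_path, "", "sets.gmt"))) == 0


class TestCollapseToGenes:
    def test_isoforms_collapse(self):
        genes, mapping = collapse_to_genes(
            ["Bin1-iso1", "Bin1-iso9", "Amph"], ["Bin1", "Bin1", "Amph"]
        )
        assert genes == {"Bin1", "Amph"}
        assert mapping["Bin1"] == ["Bin1-iso1", "Bin1-iso9"]

    def test_distinct_symbols_identity(self):
        genes, _ = collapse_to_genes(["P1", "P2"], ["A", "B"])
        assert genes == {"A", "B"}

    def test_empty_symbol_falls_back_to_protein_id(self):
        genes, _ = collapse_to_genes(["Q9X"], [""])
        assert genes == {"Q9X"}

    def test_idempotent_and_never_grows(self):
        pids = [f"P{i}" for i in range(10)]
        syms = ["G1", "G1", "G2", "", "G2", "G3", "", "G1", "G4", "G4"]
        genes, _ = collapse_to_genes(pids, syms)
        assert len(genes) <= len(pids)
        again, _ = collapse_to_genes(sorted(genes), sorted(genes))
        assert again == genes


class TestEnrichmentTableIO:
    @pytest.fixture
    def table(self, tiny_matrix, tiny_design):
        table, _ = run_enrichment_pipeline(tiny_matrix, tiny_design, PipelineParams(seed=1))
        return table

    def test_roundtrip_field_by_field(self, tmp_path, table):
        path = tmp_path / "enrichment.tsv"
        write_enrichment_table(table, path)
        back = read_enrichment_table(path)
        assert list(back["protein_id"]) == list(table["protein_id"])
        assert list(back["hit"]) == list(table["hit"])
        for col in ("diff_log2", "ratio", "p_welch", "z", "cv_bait_pct"):
            np.testing.assert_allclose(back[col], table[col], rtol=1e-11)

    def test_empty_table_writes_header_only(self, tmp_path, table):
        path = tmp_path / "empty.tsv"
        write_enrichment_table(table.iloc[0:0], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "protein_id"

    def test_non_hit_row_kept_with_false_flag(self, tmp_path, table):
        non_hit = table[~table["hit"]]
        assert len(non_hit) > 0
        path = tmp_path / "nonhit.tsv"
        write_enrichment_table(non_hit, path)
        back = read_enrichment_table(path)
        assert len(back) == len(non_hit)
        assert not back["hit"].any()
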