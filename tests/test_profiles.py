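"""Peptide table I/O and the three peptide-level quality filters."""

import numpy as np
import pandas as pd
import pytest

from dipms.profiles import (
    PeptideQuantTable,
    ProteinProfileMatrix,
    infer_protein_profiles,
    read_peptide_table,
    read_protein_matrix,
    sibling_correlation_filter,
    split_replicates,
    stretch_filter,
    write_peptide_table,
    write_protein_matrix,
)


def make_table(rows, n_fractions=6):
    """rows: list of (protein, peptide, proteotypic, replicate, values)."""
    meta = pd.DataFrame(
        [
            {"protein_id": p, "peptide_id": q, "proteotypic": t, "replicate": r}
            for p, q, t, r, _ in rows
        ]
    )
    values = np.array([v for *_, v in rows], dtype=float)
    return PeptideQuantTable(meta, values, np.arange(1, n_fractions + 1))


class TestIO:
    def test_round_trip_peptide_table(self, tmp_path):
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", [0, 5, 6, 0, 7, np.nan]),
                ("P1", "CCC", True, "rep1", [1, 4, 5, 1, 0, 0]),
                ("P2", "DDD", False, "rep1", [2, 2, 2, 2, 2, 2]),
            ]
        )
        path = tmp_path / "peps.tsv"
        write_peptide_table(table, path)
        back = read_peptide_table(path)
        assert list(back.meta["protein_id"]) == ["P1", "P1", "P2"]
        np.testing.assert_array_equal(back.intensities, table.intensities)

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tpeptide_id\tfrac_0001\tfrac_0002\nP1\tA\t1\t2\n")
        with pytest.raises(ValueError, match="proteotypic"):
            read_peptide_table(path)

    def test_duplicate_row_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table(
                [
                    ("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6]),
                    ("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6]),
                ]
            )

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table([("P1", "AAA", True, "rep1", [1, -2, 3, 4, 5, 6])])

    def test_protein_matrix_round_trip(self, tmp_path):
        matrix = ProteinProfileMatrix(
            np.array(["P1", "P2"], dtype=object),
            np.array([[1.5, 0.0, np.nan], [2.25, 3.125, 4.0]]),
            "rep2",
        )
        path = tmp_path / "prot.tsv"
        write_protein_matrix(matrix, path)
        back = read_protein_matrix(path)
        assert back.replicate_id == "rep2"
        np.testing.assert_array_equal(back.intensities, matrix.intensities)

    def test_empty_matrix_round_trip(self, tmp_path):
        matrix = ProteinProfileMatrix(
            np.array([], dtype=object), np.empty((0, 4)), "rep1"
        )
        path = tmp_path / "empty.tsv"
        write_protein_matrix(matrix, path)
        assert len(read_protein_matrix(path).protein_ids) == 0

    def test_negative_value_in_matrix_file(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text(
            "protein_id\treplicate\tfrac_0001\tfrac_0002\nP1\trep1\t1.0\t-2.0\n"
        )
        with pytest.raises(ValueError, match="line"):
            read_protein_matrix(path)


class TestStretchFilter:
    def test_isolated_detection_zeroed(self):
        table = make_table([("P1", "AAA", True, "rep1", [0, 5, 6, 0, 7, 0])])
        out = stretch_filter(table, min_consecutive=2)
        np.testing.assert_array_equal(out.intensities[0], [0, 5, 6, 0, 0, 0])

    def test_fully_detected_protein_unchanged(self):
        table = make_table([("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6])])
        out = stretch_filter(table)
        np.testing.assert_array_equal(out.intensities, table.intensities)

    def test_min_consecutive_one_is_identity(self):
        table = make_table([("P1", "AAA", True, "rep1", [0, 5, 0, 0, 7, 0])])
        out = stretch_filter(table, min_consecutive=1)
        np.testing.assert_array_equal(out.intensities, table.intensities)

    def test_protein_level_detection_uses_sibling_union(self):
        # peptide A misses fraction 2 but sibling B covers it: the run spans 1-3
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", [4, 0, 4, 0, 0, 0]),
                ("P1", "BBB", True, "rep1", [0, 4, 0, 0, 0, 0]),
            ]
        )
        out = stretch_filter(table, min_consecutive=2)
        np.testing.assert_array_equal(out.intensities[0], [4, 0, 4, 0, 0, 0])
        np.testing.assert_array_equal(out.intensities[1], [0, 4, 0, 0, 0, 0])

    @pytest.mark.parametrize("pattern", [
        [0, 5, 6, 0, 7, 0],
        [1, 0, 1, 0, 1, 0],
        [3, 3, 3, 0, 0, 2],
    ])
    def test_idempotent_and_runs_long_enough(self, pattern):
        table = make_table([("P1", "AAA", True, "rep1", pattern)])
        once = stretch_filter(table)
        twice = stretch_filter(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)
        present = once.intensities[0] > 0
        lengths = []
        i = 0
        vals = present.astype(int)
        while i < len(vals):
            if vals[i]:
                j = i
                while j < len(vals) and vals[j]:
                    j += 1
                lengths.append(j - i)
                i = j
            else:
                i += 1
        assert all(length >= 2 for length in lengths)


class TestSiblingCorrelationFilter:
    def test_anticorrelated_peptide_removed(self):
        up = [1, 2, 3, 4, 5, 6]
        down = [6, 5, 4, 3, 2, 1]
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", up),
                ("P1", "BBB", True, "rep1", up),
                ("P1", "CCC", True, "rep1", down),
            ]
        )
        out = sibling_correlation_filter(table, cutoff=0.2)
        assert sorted(out.meta["peptide_id"]) == ["AAA", "BBB"]

    def test_identical_peptides_kept(self):
        v = [1, 2, 5, 2, 1, 0]
        table = make_table(
            [("P1", "AAA", True, "rep1", v), ("P1", "BBB", True, "rep1", v)]
        )
        out = sibling_correlation_filter(table)
        assert len(out.meta) == 2

    def test_single_peptide_retained_and_flagged(self):
        table = make_table([("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6])])
        out = sibling_correlation_filter(table)
        assert len(out.meta) == 1
        assert bool(out.meta["low_evidence"].iloc[0])

    def test_never_removes_last_peptide(self):
        # two mutually anti-correlated peptides: one survives
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6]),
                ("P1", "BBB", True, "rep1", [6, 5, 4, 3, 2, 1]),
            ]
        )
        out = sibling_correlation_filter(table, cutoff=0.2)
        assert len(out.meta) == 1


class TestInferProteinProfiles:
    def test_single_proteotypic_peptide_passthrough(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        table = make_table([("P1", "AAA", True, "rep1", v)])
        matrix = infer_protein_profiles(table)
        np.testing.assert_array_equal(matrix.profile("P1"), v)

    def test_top_two_by_total_intensity(self):
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", [50, 50, 0, 0, 0, 0]),   # total 100
                ("P1", "BBB", True, "rep1", [25, 25, 0, 0, 0, 0]),   # total 50
                ("P1", "CCC", True, "rep1", [5, 5, 0, 0, 0, 0]),     # total 10
            ]
        )
        matrix = infer_protein_profiles(table, top_n=2)
        np.testing.assert_array_equal(matrix.profile("P1"), [75, 75, 0, 0, 0, 0])

    def test_nonproteotypic_only_protein_dropped(self):
        table = make_table(
            [
                ("P1", "AAA", False, "rep1", [1, 2, 3, 4, 5, 6]),
                ("P2", "BBB", True, "rep1", [1, 2, 3, 4, 5, 6]),
            ]
        )
        matrix = infer_protein_profiles(table)
        assert list(matrix.protein_ids) == ["P2"]

    def test_output_total_bounded_by_input_total(self):
        rng = np.random.default_rng(0)
        rows = [
            ("P1", f"PEP{i}", True, "rep1", rng.random(6) * 10) for i in range(5)
        ]
        table = make_table(rows)
        matrix = infer_protein_profiles(table, top_n=2)
        assert np.nansum(matrix.profile("P1")) <= np.nansum(table.intensities) + 1e-12

    def test_multi_replicate_requires_split(self):
        table = make_table(
            [
                ("P1", "AAA", True, "rep1", [1, 2, 3, 4, 5, 6]),
                ("P1", "AAA", True, "rep2", [1, 2, 3, 4, 5, 6]),
            ]
        )
        with pytest.raises(ValueError, match="replicates"):
            infer_protein_profiles(table)
        parts = split_replicates(table)
        assert sorted(parts) == ["rep1", "rep2"]
        assert all(len(t.meta) == 1 for t in parts.values())
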