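"""Data model and reader/writer round-trip behaviour."""

import numpy as np
import pandas as pd
import pytest

from nmrbind import io as nio
from nmrbind.core import (
    DecayTable,
    DispersionTable,
    ItcTable,
    SequenceRecord,
    ShiftTable,
    TitrationDesign,
    ValidationError,
)


class TestSequence:
    def test_fasta_identity_case(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nDLF\n")
        rec = nio.read_sequence(p, 435)
        assert rec.residues == "DLF"
        assert list(rec.residue_numbers) == [435, 436, 437]
        assert rec.residue_type(436) == "L"

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\ndlf\n")
        assert nio.read_sequence(p).residues == "DLF"

    def test_illegal_residue_names_position(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nDBF\n")
        with pytest.raises(nio.ParseError, match="position 436"):
            nio.read_sequence(p, 435)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text("")
        with pytest.raises(nio.ParseError):
            nio.read_sequence(p)

    def test_subsequence_numbering(self):
        rec = SequenceRecord("x", "ACDEFG", 10)
        sub = rec.subsequence(12, 14)
        assert sub.residues == "DEF" and sub.first_residue_number == 12


class TestShiftTable:
    def test_csv_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("residue,residue_type,atom,shift\n435,D,N,119.2\n")
        table = nio.read_shift_table(p, "csv")
        assert table.get(435, "N") == 119.2

    def test_sparky_line_yields_both_atoms_and_intensity(self, tmp_path):
        p = tmp_path / "p.list"
        p.write_text("Assignment w1 w2 height\nD435N-H 119.2 8.31 1.2e6\n")
        table = nio.read_shift_table(p, "sparky_list")
        assert table.get(435, "N") == 119.2
        assert table.get(435, "H") == 8.31
        assert table.intensities[435] == 1.2e6

    def test_sparky_bad_label(self, tmp_path):
        p = tmp_path / "p.list"
        p.write_text("???435N-H 119.2 8.31\n")
        with pytest.raises(nio.ParseError, match="unparsable"):
            nio.read_shift_table(p, "sparky_list")

    def test_duplicate_residue_atom_is_error(self):
        with pytest.raises(ValidationError, match="duplicate"):
            ShiftTable.from_records(
                [(435, "D", "N", 119.2), (435, "D", "N", 120.0)]
            )

    def test_unknown_atom_is_error(self):
        with pytest.raises(ValidationError, match="unknown atom"):
            ShiftTable.from_records([(1, "A", "HB", 1.2)])

    def test_out_of_range_amide_shift_warns_not_errors(self):
        with pytest.warns(UserWarning, match="outside"):
            table = ShiftTable.from_records([(1, "A", "H", 22.0)])
        assert len(table) == 1

    def test_nmrstar_loop(self, tmp_path):
        p = tmp_path / "x.str"
        p.write_text(
            "data_x\nloop_\n_Atom_chem_shift.ID\n_Atom_chem_shift.Seq_ID\n"
            "_Atom_chem_shift.Comp_ID\n_Atom_chem_shift.Atom_ID\n"
            "_Atom_chem_shift.Val\n"
            "1 435 ASP N 119.2\n2 435 ASP CA 54.1\n3 436 LEU HB2 1.5\nstop_\n"
        )
        table = nio.read_shift_table(p, "nmrstar_loop")
        assert table.get(435, "N") == 119.2
        assert table.get(435, "CA") == 54.1
        assert table.get(436, "CB") is None  # side-chain atoms ignored

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            nio.read_shift_table(tmp_path / "x", "xlsx")


class TestDesign:
    def test_percent_converts_to_um(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text(
            "a_total_um: 100\npartner_id: CHC\npoints:\n"
            "  - {label: '0%', percent: 0}\n  - {label: '50%', percent: 50}\n"
            "  - {label: 'abs', b_total_um: 37.5}\n"
        )
        d = nio.read_design(p)
        assert d.b_total("50%") == 50.0
        assert d.b_total("abs") == 37.5

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            TitrationDesign(100.0, (("a", 0.0), ("a", 1.0)))

    def test_nonpositive_observed_concentration_rejected(self):
        with pytest.raises(ValidationError):
            TitrationDesign(0.0, (("a", 0.0),))


class TestTableValidation:
    def test_decay_needs_three_delays(self):
        frame = pd.DataFrame(
            [(1, 0.01, 9.0, 1.0), (1, 0.02, 8.0, 1.0)], columns=DecayTable.COLUMNS
        )
        with pytest.raises(ValidationError, match="3 distinct delays"):
            DecayTable(frame)

    def test_dispersion_error_floor_applied(self):
        frame = pd.DataFrame(
            [(1, 600.0, 0.032, 1000.0, 10.0, 0.1)], columns=DispersionTable.COLUMNS
        )
        table = DispersionTable(frame)
        assert table.frame["error"].iloc[0] == 0.5

    def test_dispersion_requires_full_cycle(self):
        frame = pd.DataFrame(
            [(1, 600.0, 0.032, 10.0, 10.0, 0.5)], columns=DispersionTable.COLUMNS
        )
        with pytest.raises(ValidationError, match="cycle"):
            DispersionTable(frame)


class TestRoundTrips:
    def test_shift_table(self, tmp_path):
        table = ShiftTable.from_records(
            [(435, "D", "N", 119.215), (435, "D", "H", 8.31), (436, "L", "CA", 55.1)]
        )
        nio.write_shift_table(table, tmp_path / "s.tsv")
        back = nio.read_shift_table_tsv(tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(table.frame, back.frame)

    def test_decay_table(self, tmp_path, decay_table):
        nio.write_decay_table(decay_table, tmp_path / "d.tsv")
        back = nio.read_decay_table(tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(decay_table.frame, back.frame)

    def test_dispersion_table(self, tmp_path):
        rows = [(1, 600.0, 0.032, n / 0.032, 8.0 + n / 10, 0.5) for n in (1, 2, 4)]
        table = DispersionTable(pd.DataFrame(rows, columns=DispersionTable.COLUMNS))
        nio.write_dispersion_table(table, tmp_path / "x.tsv")
        back = nio.read_dispersion_table(tmp_path / "x.tsv")
        pd.testing.assert_frame_equal(table.frame, back.frame)

    def test_itc_table(self, tmp_path, itc_design):
        nio.write_itc_table(itc_design, tmp_path / "itc.csv")
        back = nio.read_itc_table(tmp_path / "itc.csv")
        assert back == itc_design

    def test_empty_table_writes_header_only(self, tmp_path, caplog):
        empty = ShiftTable(pd.DataFrame(columns=ShiftTable.COLUMNS))
        nio.write_shift_table(empty, tmp_path / "e.tsv")
        text = (tmp_path / "e.tsv").read_text()
        assert text.splitlines()[0].startswith("residue")
        assert len(text.splitlines()) == 1


class TestReaderTotality:
    """Mutated inputs either parse or raise a located ParseError."""

    @pytest.mark.parametrize("mutation", ["drop_field", "garbage_number", "blank", "dup"])
    def test_csv_mutations(self, tmp_path, mutation):
        base = "residue,residue_type,atom,shift\n435,D,N,119.2\n436,L,CA,55.1\n"
        if mutation == "drop_field":
            text = base.replace("436,L,CA,55.1", "436,L,CA")
        elif mutation == "garbage_number":
            text = base.replace("119.2", "not_a_number")
        elif mutation == "blank":
            text = base + "\n\n"
        else:
            text = base + "435,D,N,119.2\n"
        p = tmp_path / "m.csv"
        p.write_text(text)
        try:
            nio.read_shift_table(p, "csv")
        except (nio.ParseError, ValueError):
            pass  # a located parse/validation error is the contract
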