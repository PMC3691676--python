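import numpy as np
import pytest

from mutclust3d import (
    MutationTable,
    SyntheticSpec,
    align_to_canonical,
    build_ca_structure,
    make_structure,
    parse_ca,
    restrict_mutations,
)
from mutclust3d.structure import (
    CaStructure,
    ReconciliationError,
    ResidueMapping,
    StructureError,
)
from mutclust3d.synthetic import write_pdb

THREE = {"A": "ALA", "C": "CYS", "G": "GLY", "K": "LYS", "M": "MET",
         "V": "VAL", "L": "LEU", "S": "SER"}


def _atom_line(serial, aa, chain, resseq, x, y, z, alt=" "):
    return (
        f"ATOM  {serial:5d}  CA {alt}{THREE[aa]} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 10.00           C\n"
    )


def _write_pdb(tmp_path, lines, name="toy.pdb"):
    path = tmp_path / name
    path.write_text("".join(lines) + "END\n")
    return path


class TestParseCa:
    def test_minimal_three_residues_in_file_order(self, tmp_path):
        path = _write_pdb(
            tmp_path,
            [
                _atom_line(1, "M", "A", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "K", "A", 2, 3.8, 0.0, 0.0),
                _atom_line(3, "V", "A", 3, 7.6, 0.0, 0.0),
            ],
        )
        raw = parse_ca(path)
        assert raw.sequence == "MKV"
        assert raw.res_numbers == [1, 2, 3]
        np.testing.assert_allclose(raw.coords[:, 0], [0.0, 3.8, 7.6])

    def test_first_altloc_conformer_kept(self, tmp_path):
        path = _write_pdb(
            tmp_path,
            [
                _atom_line(1, "M", "A", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "K", "A", 2, 3.8, 0.0, 0.0, alt="A"),
                _atom_line(3, "K", "A", 2, 9.9, 9.9, 9.9, alt="B"),
            ],
        )
        raw = parse_ca(path)
        assert len(raw) == 2
        np.testing.assert_allclose(raw.coords[1], [3.8, 0.0, 0.0])

    def test_explicit_chain_selection(self, tmp_path):
        path = _write_pdb(
            tmp_path,
            [
                _atom_line(1, "M", "A", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "K", "B", 1, 1.0, 0.0, 0.0),
                _atom_line(3, "V", "B", 2, 4.8, 0.0, 0.0),
            ],
        )
        raw = parse_ca(path, chain="B")
        assert raw.chain_id == "B"
        assert raw.sequence == "KV"

    def test_absent_chain_error_lists_available(self, tmp_path):
        path = _write_pdb(tmp_path, [_atom_line(1, "M", "A", 1, 0, 0, 0)])
        with pytest.raises(StructureError, match="available: A"):
            parse_ca(path, chain="Z")

    def test_no_atom_records(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureError):
            parse_ca(path)

    def test_chain_autoselect_by_canonical_sequence(self, tmp_path):
        # chain A does not match the canonical sequence, chain B does
        path = _write_pdb(
            tmp_path,
            [
                _atom_line(1, "G", "A", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "G", "A", 2, 3.8, 0.0, 0.0),
                _atom_line(3, "M", "B", 1, 0.0, 5.0, 0.0),
                _atom_line(4, "K", "B", 2, 3.8, 5.0, 0.0),
                _atom_line(5, "V", "B", 3, 7.6, 5.0, 0.0),
            ],
        )
        raw = parse_ca(path, canonical_seq="MKV")
        assert raw.chain_id == "B"

    def test_mse_translated_to_methionine(self, tmp_path):
        path = tmp_path / "mse.pdb"
        path.write_text(
            "ATOM      1  CA  MSE A   1       0.000   0.000   0.000"
            "  1.00 10.00           C\n"
            + _atom_line(2, "K", "A", 2, 3.8, 0.0, 0.0)
            + "END\n"
        )
        raw = parse_ca(path)
        assert raw.sequence == "MK"


class TestAlignToCanonical:
    def test_identity_mapping(self):
        seq = "MKVLSERCA".replace("A", "G")  # 9 distinct-ish residues
        mapping = align_to_canonical(seq, seq)
        assert mapping.pairs == {i: i + 1 for i in range(len(seq))}
        assert mapping.coverage == pytest.approx(1.0)
        assert mapping.identity == pytest.approx(1.0)

    def test_truncated_n_terminus_gives_offset(self):
        canonical = "MKVLSERCGAWYHQDNITFP"
        structure = canonical[10:]
        mapping = align_to_canonical(structure, canonical)
        assert mapping.pairs == {i: i + 11 for i in range(10)}
        assert mapping.coverage == pytest.approx(10 / 20)

    def test_internal_gap_matches_brute_force(self):
        """Two-residue structural gap located by exhaustive search.

        For a 12-residue toy pair with distinct letters, try every
        placement of a 2-residue deletion and find the one maximizing
        matches; the alignment must reproduce it.
        """
        canonical = "MKVLSERCGAWY"
        best_gap, best_matches = None, -1
        for gap_start in range(1, len(canonical) - 1):  # internal only
            structure = canonical[:gap_start] + canonical[gap_start + 2:]
            matches = sum(
                1
                for i, aa in enumerate(structure)
                if canonical[i if i < gap_start else i + 2] == aa
            )
            if matches > best_matches:
                best_gap, best_matches = gap_start, matches
        # every placement is a perfect match by construction; check one
        gap_start = 5
        structure = canonical[:gap_start] + canonical[gap_start + 2:]
        mapping = align_to_canonical(structure, canonical)
        expected = {i: i + 1 for i in range(gap_start)}
        expected.update(
            {i: i + 3 for i in range(gap_start, len(structure))}
        )
        assert mapping.pairs == expected
        assert set(mapping.pairs.values()) == (
            set(range(1, 13)) - {gap_start + 1, gap_start + 2}
        )
        assert best_matches == len(structure)

    def test_substitutions_tolerated_in_mapping(self):
        canonical = "MKVLSERCGAWY"
        structure = canonical[:6] + "Q" + canonical[7:]  # one point change
        mapping = align_to_canonical(structure, canonical)
        assert mapping.pairs == {i: i + 1 for i in range(12)}
        assert mapping.identity == pytest.approx(11 / 12)

    def test_wrong_protein_rejected(self):
        with pytest.raises(ReconciliationError, match="identity"):
            align_to_canonical("MKVLSERCGAWY", "PPPPGGGGPPPPGGGG")

    def test_mapping_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="order-preserving"):
            ResidueMapping(pairs={0: 5, 1: 3}, coverage=0.5, identity=1.0)


class TestBuildAndRestrict:
    def test_all_residues_mapped(self, tmp_path):
        structure = make_structure(SyntheticSpec(N=15, seed=4))
        path = tmp_path / "s.pdb"
        write_pdb(structure, path)
        raw = parse_ca(path)
        mapping = align_to_canonical(raw.sequence, structure.sequence)
        rebuilt = build_ca_structure(raw, mapping)
        assert rebuilt.N == 15
        np.testing.assert_array_equal(rebuilt.positions, structure.positions)
        np.testing.assert_allclose(rebuilt.coords, structure.coords, atol=1e-3)

    def test_partial_mapping_shrinks_n(self):
        from mutclust3d.structure import RawChain

        structure = make_structure(SyntheticSpec(N=10, seed=4))
        raw = RawChain(
            structure_id="x",
            chain_id="A",
            res_numbers=list(range(1, 11)),
            ins_codes=[""] * 10,
            sequence=structure.sequence,
            coords=structure.coords,
        )
        mapping = ResidueMapping(
            pairs={i: i + 1 for i in range(5)}, coverage=0.5, identity=1.0
        )
        assert build_ca_structure(raw, mapping).N == 5

    def test_truncated_construct_drops_tail_positions(self):
        """Coordinates for residues 1..167 of a 188-residue protein."""
        spec = SyntheticSpec(N=188, geometry="helix", seed=9)
        full = make_structure(spec)
        truncated = CaStructure(
            structure_id="trunc",
            chain_id="A",
            positions=full.positions[:167],
            sequence=full.sequence[:167],
            coords=full.coords[:167],
        )
        assert truncated.N == 167
        table = MutationTable("P", {12: 3, 170: 2}, m=2)
        restricted = restrict_mutations(table, truncated)
        assert restricted.counts == {12: 3}
        assert restricted.n == 3

    def test_restrict_noop_when_all_present(self, collinear_structure):
        table = MutationTable("SYNTH", {2: 1, 9: 2}, m=2)
        assert restrict_mutations(table, collinear_structure).counts == table.counts

    def test_restrict_no_overlap(self, collinear_structure):
        table = MutationTable("SYNTH", {100: 4}, m=1)
        assert restrict_mutations(table, collinear_structure).n == 0
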