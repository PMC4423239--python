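"""Structure model: I/O round-trips, mirroring, chirality, sequence parsing."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from spiegelstruct import fixtures as fx
from spiegelstruct import sequences
from spiegelstruct.model import (
    AtomRecord,
    Chain,
    ResidueRecord,
    StructureModel,
    classify_residue_kind,
    detect_chirality,
    mirror_structure,
    parse_mixed_sequence,
    read_structure,
    structure_summary,
    write_structure,
)


def _mini_structure():
    water = ResidueRecord("HOH", 1, kind="water", atoms=[AtomRecord("O", "O", [0, 0, 0])])
    mg = ResidueRecord("MG", 2, kind="metal_ion", atoms=[AtomRecord("MG", "Mg", [5, 0, 0])])
    g = fx.make_nucleotide("G", number=3)
    return StructureModel([Chain("A", [water, mg, g])], identifier="mini")


def test_residue_kind_typing_by_construction(tmp_path):
    path = tmp_path / "mini.pdb"
    write_structure(_mini_structure(), path)
    model = read_structure(path)
    kinds = [r.kind for r in model.residues()]
    assert sorted(kinds) == ["metal_ion", "ribonucleotide", "water"]


def test_kind_precedence_o2prime_heuristic():
    ring = {"C1'", "C2'", "C3'", "C4'", "O4'"}
    assert classify_residue_kind("XNA", ring | {"O2'"}) == "ribonucleotide"
    assert classify_residue_kind("XNA", ring) == "deoxyribonucleotide"
    assert classify_residue_kind("G", set(), entity_kind="ribonucleotide") == "ribonucleotide"


@pytest.mark.parametrize("fmt,tol", [("pdb", 1e-3), ("cif", 1e-6)])
def test_round_trip_preserves_coordinates(tmp_path, duplex8, fmt, tol):
    path = tmp_path / f"dup.{fmt}"
    write_structure(duplex8, path)
    back = read_structure(path)
    assert back.n_atoms == duplex8.n_atoms
    assert np.abs(back.coordinates() - duplex8.coordinates()).max() <= tol
    assert [r.author_number for r in back.residues()] == [
        r.author_number for r in duplex8.residues()
    ]


def test_mirror_is_involution_and_isometry(duplex8):
    m = mirror_structure(duplex8)
    mm = mirror_structure(m)
    assert np.array_equal(mm.coordinates(), duplex8.coordinates())
    # reflection preserves every interatomic distance exactly
    assert np.abs(pdist(m.coordinates()) - pdist(duplex8.coordinates())).max() == 0.0


def test_mirror_negates_torsions(duplex8):
    from spiegelstruct.conform import glycosidic_chi

    res = duplex8.chains[0].residues[0]
    res_m = mirror_structure(duplex8).chains[0].residues[0]
    chi = glycosidic_chi(res, frame="as-deposited")
    chi_m = glycosidic_chi(res_m, frame="as-deposited")
    assert chi_m == pytest.approx(-chi, abs=1e-9)


def test_chirality_detection_and_mirror_flip(duplex8):
    assert all(detect_chirality(r) == "D" for r in duplex8.residues())
    mirrored = mirror_structure(duplex8)
    assert all(detect_chirality(r) == "L" for r in mirrored.residues())
    assert all(r.chirality == "L" for r in mirrored.residues())


def test_chirality_matches_natural_nucleotide_templates():
    # external oracle: CCD ideal coordinates are natural D-nucleotides
    import biotite.structure.info as info

    for name in ("G", "A", "C", "U", "DG", "DT"):
        res = info.residue(name)
        atoms = [
            AtomRecord(n, e, c)
            for n, e, c in zip(res.atom_name, res.element, res.coord)
            if e not in ("H", "D")
        ]
        rr = ResidueRecord(name, 1, kind="ribonucleotide", atoms=atoms)
        assert detect_chirality(rr) == "D", name


def test_chirality_incomplete_sugar_warns():
    rr = ResidueRecord("G", 1, kind="ribonucleotide", atoms=[AtomRecord("C1'", "C", [0, 0, 0])])
    with pytest.warns(UserWarning):
        assert detect_chirality(rr) == "not_applicable"


class TestMixedSequence:
    def test_published_40mer(self):
        seq = sequences.nox_d20()
        assert seq.length == 40
        assert seq.deoxy_positions == [7, 14, 15, 28, 30, 38]
        bases = [b for b, _ in seq.nucleotides]
        assert [bases[i - 1] for i in (17, 19, 25, 27)] == ["G"] * 4
        assert [bases[i - 1] for i in (18, 22, 26, 32)] == ["G"] * 4

    def test_published_44mer_all_ribo(self):
        seq = sequences.nox_d19()
        assert seq.length == 44
        assert seq.deoxy_positions == []

    def test_empty(self):
        assert parse_mixed_sequence("").length == 0

    @pytest.mark.parametrize("bad", ["AC(dU", "AC)G", "AX", "(dZ)", "(U)"])
    def test_errors_carry_offset(self, bad):
        with pytest.raises(ValueError, match="offset"):
            parse_mixed_sequence(bad)


def test_unknown_residue_warns_not_errors(tmp_path):
    pdb = tmp_path / "odd.pdb"
    pdb.write_text(
        "HETATM    1  C1  XYZ A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    with pytest.warns(UserWarning, match="unknown residue"):
        model = read_structure(pdb)
    assert [r.kind for r in model.residues()] == ["other"]


def test_unparseable_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a coordinate file\n")
    with pytest.raises((ValueError, FileNotFoundError)):
        read_structure(bad, fmt="mmcif")


def test_altloc_policy_keeps_highest_occupancy(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  O  AHOH A   1       0.000   0.000   0.000  0.30  0.00           O\n"
        "ATOM      2  O  BHOH A   1       1.000   0.000   0.000  0.70  0.00           O\n"
        "END\n"
    )
    model = read_structure(pdb)
    atoms = list(model.atoms())
    assert len(atoms) == 1 and atoms[0].position[0] == pytest.approx(1.0)
    both = read_structure(pdb, keep_altlocs=True)
    assert both.n_atoms == 2


def test_summary_reports_chain_content(duplex8_l):
    s = structure_summary(duplex8_l)
    assert s["chains"][0]["n_nucleotides"] == 8
    assert s["chains"][0]["chiralities"] == ["L"]
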