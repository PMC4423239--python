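"""Hydrogen bonds, base pairs, stacking, tetrads and quadruplex assembly."""

import numpy as np
import pytest

from spiegelstruct import fixtures as fx
from spiegelstruct.geometry import random_rotation
from spiegelstruct.model import (
    AtomRecord,
    Chain,
    ResidueRecord,
    StructureModel,
    mirror_structure,
)
from spiegelstruct.pairing import (
    assemble_quadruplex,
    detect_base_pairs,
    detect_hbonds,
    detect_stacking,
    detect_tetrads,
    helix_handedness,
)


def _two_waters(distance):
    w1 = ResidueRecord("HOH", 1, kind="water", atoms=[AtomRecord("O", "O", [0, 0, 0])])
    w2 = ResidueRecord("HOH", 2, kind="water", atoms=[AtomRecord("O", "O", [distance, 0, 0])])
    return StructureModel([Chain("W", [w1, w2])])


@pytest.mark.parametrize("distance,n", [(2.8, 1), (5.0, 0), (3.6, 0)])
def test_water_hbond_cutoff(distance, n):
    assert len(detect_hbonds(_two_waters(distance))) == n


def test_hbond_cutoff_range_enforced():
    with pytest.raises(ValueError):
        detect_hbonds(_two_waters(2.8), cutoff=10.0)


def test_empty_selection_gives_empty_list(duplex8):
    assert detect_hbonds(duplex8, selection=set()) == []


def test_gc_pair_canonical_three_hbonds():
    pair = fx.make_base_pair("G")
    hb = detect_hbonds(pair)
    atom_pairs = {frozenset({h.donor.atom_name, h.acceptor.atom_name}) for h in hb}
    assert {frozenset({"N4", "O6"}), frozenset({"N1", "N3"}), frozenset({"O2", "N2"})} <= atom_pairs
    assert len([h for h in hb if h.donor.chain != h.acceptor.chain]) == 3


def test_duplex_has_exactly_eight_wc_pairs(duplex8):
    pairs = detect_base_pairs(duplex8)
    assert len(pairs) == 8
    assert all(p.pair_class == "watson_crick" for p in pairs)


def test_pair_detection_mirror_invariant(duplex8):
    a = [(p.residue_a, p.residue_b, p.pair_class) for p in detect_base_pairs(duplex8)]
    b = [(p.residue_a, p.residue_b, p.pair_class) for p in detect_base_pairs(mirror_structure(duplex8))]
    assert a == b


def test_pair_counts_stable_under_rigid_motion(duplex8, rng):
    """100 seeded random placements keep all construction counts."""
    coords0 = duplex8.coordinates()
    for _ in range(100):
        rot = random_rotation(rng)
        shift = rng.uniform(-50, 50, 3)
        moved = duplex8.copy()
        for atom, pos in zip(moved.atoms(), coords0 @ rot.T + shift):
            atom.position = pos
        assert len(detect_base_pairs(moved)) == 8


def test_duplex_has_no_tetrads(duplex8):
    assert detect_tetrads(duplex8) == []


def test_consecutive_intrastrand_bases_stacked(duplex8):
    stacked = set(detect_stacking(duplex8))
    for chain in duplex8.chains:
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            key = tuple(sorted([(chain.name, r1.author_number), (chain.name, r2.author_number)]))
            assert key in stacked


def test_distant_bases_not_stacked():
    a = fx.make_nucleotide("G", number=1)
    b = fx.make_nucleotide("G", number=2)
    for atom in b.atoms:
        atom.position = atom.position + np.array([10.0, 0.0, 0.0])
    model = StructureModel([Chain("A", [a]), Chain("B", [b])])
    assert detect_stacking(model) == []


class TestTetrads:
    def test_single_ideal_tetrad(self):
        model = fx.make_tetrad_stack(1, ion=None)
        tets = detect_tetrads(model)
        assert len(tets) == 1
        assert {n for _, n in tets[0].guanines} == {1, 2, 3, 4}

    def test_two_tetrad_fixture(self, tetrad45):
        tets = detect_tetrads(tetrad45)
        assert len(tets) == 2
        sets = {frozenset(n for _, n in t.guanines) for t in tets}
        assert sets == {frozenset({1, 2, 3, 4}), frozenset({5, 6, 7, 8})}

    def test_tetrad_sets_mirror_invariant(self, tetrad45):
        a = {frozenset(t.guanines) for t in detect_tetrads(tetrad45)}
        b = {frozenset(t.guanines) for t in detect_tetrads(mirror_structure(tetrad45))}
        assert a == b

    @pytest.mark.parametrize("twist", [30.0, 45.0])
    def test_constructed_twist_recovered(self, twist):
        model = fx.make_tetrad_stack(2, twist=twist, ion=None)
        quad = assemble_quadruplex(model, detect_tetrads(model))
        assert len(quad.tetrads) == 2
        assert quad.twist_angles[0] == pytest.approx(twist, abs=0.5)

    def test_channel_ion_listed(self, tetrad45):
        quad = assemble_quadruplex(tetrad45, detect_tetrads(tetrad45))
        assert len(quad.channel_ions) == 1
        assert quad.channel_ions[0].residue_name == "CA"

    def test_unstackable_tetrads_not_assembled(self):
        model = fx.make_tetrad_stack(2, twist=45.0, rise=2.9, ion=None)
        # move the second tetrad far away
        for res in model.chain("Q").residues[4:]:
            for atom in res.atoms:
                atom.position = atom.position + np.array([0.0, 0.0, 30.0])
        quad = assemble_quadruplex(model, detect_tetrads(model))
        assert quad.twist_angles == []


def test_helix_handedness_flips_with_chirality(duplex8, duplex8_l):
    assert helix_handedness(duplex8, "A") == "right"
    assert helix_handedness(duplex8_l, "A") == "left"
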