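"""Solvent-accessible and buried surface areas."""

import numpy as np
import pytest

from spiegelstruct import fixtures as fx
from spiegelstruct.geometry import random_rotation
from spiegelstruct.model import AtomRecord, Chain, ResidueRecord, StructureModel, mirror_structure
from spiegelstruct.surface import (
    DEFAULT_PROBE,
    VDW_RADII,
    buried_surface,
    footprint_overlap,
    sasa,
    sphere_points,
)


def _atom_model(positions, elements, chain="X"):
    atoms = [AtomRecord(f"{e}{i+1}", e, p) for i, (e, p) in enumerate(zip(elements, positions))]
    return StructureModel([Chain(chain, [ResidueRecord("CLU", 1, kind="other", atoms=atoms)])])


def _dense_oracle_sasa(model, probe=DEFAULT_PROBE, n=10_000, seed=99):
    """Independent high-density quadrature: seeded random points per sphere."""
    rng = np.random.default_rng(seed)
    atoms = list(model.atoms())
    pos = np.array([a.position for a in atoms])
    radii = np.array([VDW_RADII[a.element] for a in atoms]) + probe
    total = 0.0
    for i in range(len(atoms)):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = pos[i] + radii[i] * pts
        buried = np.zeros(n, bool)
        for j in range(len(atoms)):
            if j != i:
                buried |= np.linalg.norm(pts - pos[j], axis=1) < radii[j]
        total += 4 * np.pi * radii[i] ** 2 * (~buried).mean()
    return total


def test_sphere_lattice_is_deterministic_and_unit():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.array_equal(pts, sphere_points(960))


def test_single_atom_matches_analytic_sphere():
    model = _atom_model([[0, 0, 0]], ["C"])
    result = sasa(model, n_points=960)
    analytic = 4 * np.pi * (VDW_RADII["C"] + DEFAULT_PROBE) ** 2
    assert abs(result.total - analytic) / analytic < 0.01


def test_two_distant_atoms_are_additive():
    model = _atom_model([[0, 0, 0], [50, 0, 0]], ["C", "O"])
    total = sasa(model).total
    expected = sum(4 * np.pi * (VDW_RADII[e] + DEFAULT_PROBE) ** 2 for e in ("C", "O"))
    assert total == pytest.approx(expected, rel=0.01)


def test_fully_buried_atom_has_zero_area():
    shell = 2.0 * sphere_points(30)
    model = _atom_model(np.vstack([[0, 0, 0], shell]), ["C"] * 31)
    result = sasa(model)
    assert result.atom_areas[0] == 0.0


def test_cluster_agrees_with_dense_quadrature_oracle():
    model = fx.make_sphere_cluster(20, seed=3)
    mine = sasa(model, n_points=960).total
    oracle = _dense_oracle_sasa(model)
    assert abs(mine - oracle) / oracle < 0.02


def test_probe_range_enforced():
    with pytest.raises(ValueError):
        sasa(_atom_model([[0, 0, 0]], ["C"]), probe=0.5)


def test_unknown_element_warns_and_uses_default():
    model = _atom_model([[0, 0, 0]], ["XX"])
    with pytest.warns(UserWarning, match="unknown element"):
        result = sasa(model)
    assert result.total > 0


def test_sasa_invariant_under_rotation_and_mirror(rng):
    model = fx.make_sphere_cluster(15, seed=11)
    ref = sasa(model).total
    rot, shift = random_rotation(rng), rng.uniform(-20, 20, 3)
    moved = model.copy()
    for atom in moved.atoms():
        atom.position = rot @ atom.position + shift
    assert sasa(moved).total == pytest.approx(ref, rel=1e-6)
    assert sasa(mirror_structure(model)).total == pytest.approx(ref, rel=1e-6)


class TestBuriedSurface:
    def _two_chain_model(self, separation):
        a = _atom_model([[0, 0, 0]], ["O"], chain="A")
        b = _atom_model([[separation, 0, 0]], ["O"], chain="B")
        return StructureModel(a.chains + b.chains)

    def test_separated_chains_zero_bsa(self):
        rep = buried_surface(self._two_chain_model(50.0), {"A"}, {"B"})
        assert rep.bsa_total == 0.0
        assert rep.footprint_a == {} and rep.footprint_b == {}

    def test_two_sphere_overlap_matches_cap_closed_form(self):
        d = 3.0
        rep = buried_surface(self._two_chain_model(d), {"A"}, {"B"})
        r_exp = VDW_RADII["O"] + DEFAULT_PROBE
        cap_area = 2 * np.pi * r_exp * (r_exp - d / 2)  # spherical cap, equal radii
        assert rep.bsa_total == pytest.approx(2 * cap_area, rel=0.02)

    def test_bsa_symmetric(self, duplex8):
        ab = buried_surface(duplex8, {"A"}, {"B"})
        ba = buried_surface(duplex8, {"B"}, {"A"})
        assert ab.bsa_total == ba.bsa_total

    def test_overlapping_selections_rejected(self, duplex8):
        with pytest.raises(ValueError, match="overlap"):
            buried_surface(duplex8, {"A"}, {"A", "B"})

    def test_translation_apart_never_increases_bsa(self):
        base = fx.make_sphere_cluster(10, seed=4)
        other = fx.make_sphere_cluster(10, seed=5)
        values = []
        for shift in (2.0, 4.0, 6.0, 9.0, 14.0):
            b = other.copy()
            b.chains[0].name = "B"
            for atom in b.atoms():
                atom.position = atom.position + np.array([shift, 0, 0])
            model = StructureModel(base.copy().chains + b.chains)
            values.append(buried_surface(model, {"X"}, {"B"}).bsa_total)
        assert all(x >= y - 1e-9 for x, y in zip(values, values[1:]))
        assert values[-1] == 0.0

    def test_duplex_interface_footprints_nonempty(self, duplex8):
        rep = buried_surface(duplex8, {"A"}, {"B"})
        assert rep.bsa_total > 100.0
        assert set(rep.footprint_a) and set(rep.footprint_b)


@pytest.mark.parametrize(
    "a,b,jaccard",
    [({1, 2, 3}, {1, 2, 3}, 1.0), ({1, 2}, {3, 4}, 0.0), ({1, 2, 3}, {2, 3, 4}, 0.5)],
)
def test_footprint_overlap_jaccard(a, b, jaccard):
    res = footprint_overlap(a, b)
    assert res["jaccard"] == pytest.approx(jaccard)
    assert res["jaccard"] == footprint_overlap(b, a)["jaccard"]
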