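"""Ion coordination spheres and species discrimination."""

import numpy as np
import pytest

from spiegelstruct import fixtures as fx
from spiegelstruct.geometry import random_rotation
from spiegelstruct.ions import (
    DEFAULT_SPECIES_TABLE,
    IonSite,
    colinearity_deviation,
    coordination_sphere,
    ion_report,
    score_ion_identity,
    survey_ions,
)
from spiegelstruct.model import mirror_structure
from spiegelstruct.pairing import AtomRef


def _site(mean, cn):
    model = fx.make_ion_site("CA", cn, mean)
    return coordination_sphere(model, model.metal_ions()[0])


def test_ideal_octahedral_site():
    model = fx.make_ion_site("MG", 6, 2.08)
    site = coordination_sphere(model, model.metal_ions()[0])
    assert site.coordination_number == 6
    assert site.mean_distance == pytest.approx(2.08, abs=1e-9)
    assert site.sd_distance == pytest.approx(0.0, abs=1e-9)
    assert all(cls == "water" for _, _, cls in site.ligands)


def test_cutoff_range_enforced():
    model = fx.make_ion_site("MG", 6, 2.08)
    with pytest.raises(ValueError):
        coordination_sphere(model, model.metal_ions()[0], cutoff=4.0)


def test_channel_ion_eight_guanine_o6(tetrad45):
    site = coordination_sphere(tetrad45, tetrad45.metal_ions()[0])
    assert site.coordination_number == 8
    assert all(cls == "base_O" and ref.atom_name == "O6" for ref, _, cls in site.ligands)
    assert site.mean_distance == pytest.approx(2.48, abs=0.02)


class TestSpeciesScoring:
    def test_k_distance_scores_zero(self):
        site = score_ion_identity(_site(2.81, 7))
        assert site.species_scores["K"] == pytest.approx(0.0, abs=1e-9)
        assert site.best_species == "K"
        assert site.assigned_species == "K"

    def test_mg_distance_and_cn(self):
        site = score_ion_identity(_site(2.08, 6))
        assert site.best_species == "MG"
        assert site.assigned_species == "MG"

    def test_ca_vs_k_discrimination_with_na_ambiguity(self):
        # z-scores by direct arithmetic: Ca 0.364, Na 0.90, K 3.4, Mg 6.5
        site = score_ion_identity(_site(2.47, 7))
        assert site.best_species == "CA"
        assert site.species_scores["CA"] == pytest.approx(abs(2.47 - 2.43) / 0.11, abs=1e-6)
        assert site.species_scores["K"] == pytest.approx(abs(2.47 - 2.81) / 0.10, abs=1e-6)
        assert site.species_scores["K"] > 3.0
        # Na cannot be excluded on geometry: honest ambiguity
        assert site.assigned_species == "ambiguous"
        assert site.species_scores["NA"] - site.species_scores["CA"] < 1.0

    def test_score_minimised_at_species_mean(self):
        for sp, entry in DEFAULT_SPECIES_TABLE.items():
            cn = entry.cn_range[0]
            site = score_ion_identity(_site(entry.mu, max(cn, 4)))
            assert site.species_scores[sp] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_ligands_rejected(self):
        site = IonSite(ion=AtomRef("I", 1, "CA", "CA"),
                       ligands=[(AtomRef("W", 1, "HOH", "O"), 2.4, "water")] * 2)
        with pytest.raises(ValueError):
            score_ion_identity(site)


@pytest.mark.parametrize("species,cn,jitter", [("MG", 6, 0.06), ("K", 7, 0.10)])
def test_classifier_recovery_rate(species, cn, jitter):
    """Sites drawn at the species' survey statistics are recovered >= 95%."""
    hits = 0
    n = 200
    for seed in range(n):
        model = fx.make_ion_site(species, cn, DEFAULT_SPECIES_TABLE[species].mu,
                                 jitter_sd=jitter, seed=seed)
        site = score_ion_identity(coordination_sphere(model, model.metal_ions()[0]))
        hits += site.best_species == species
    assert hits / n >= 0.95


def test_ca_generating_sites_prefer_ca_but_flag_na():
    model = fx.make_ion_site("CA", 7, 2.47, jitter_sd=0.05, seed=1)
    site = score_ion_identity(coordination_sphere(model, model.metal_ions()[0]))
    assert site.best_species == "CA"
    assert site.species_scores["CA"] < site.species_scores["K"]
    assert site.assigned_species == "ambiguous"


def test_sphere_invariant_under_mirror_and_rigid_motion(rng):
    model = fx.make_ion_site("MG", 6, 2.08, jitter_sd=0.03, seed=7)
    ref = coordination_sphere(model, model.metal_ions()[0])
    mirrored = coordination_sphere(mirror_structure(model), mirror_structure(model).metal_ions()[0])
    assert mirrored.distances == pytest.approx(ref.distances, abs=1e-12)
    rot, shift = random_rotation(rng), rng.uniform(-30, 30, 3)
    moved = model.copy()
    for atom in moved.atoms():
        atom.position = rot @ atom.position + shift
    moved_site = coordination_sphere(moved, moved.metal_ions()[0])
    assert moved_site.distances == pytest.approx(ref.distances, abs=1e-9)


def test_survey_attribution(tetrad45):
    sites = survey_ions(tetrad45)
    assert len(sites) == 1
    assert sites[0].attributed_chain == "Q"


def test_survey_isolated_ion_unattributed():
    model = fx.make_ion_site("MG", 6, 2.08)
    sites = survey_ions(model)
    assert sites[0].attributed_chain is None  # waters never attribute


def test_colinearity_deviation():
    line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
    assert colinearity_deviation(line) == pytest.approx(0.0, abs=1e-12)
    bent = np.array([[0, 0, 0], [1, 0, 1.0], [2, 0, 0]])
    assert colinearity_deviation(bent) > 0.5


def test_ion_report_columns(tetrad45):
    table = ion_report(survey_ions(tetrad45))
    assert {"ion", "cn", "mean_distance", "assigned_species", "min_distance", "max_distance"} <= set(table.columns)
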