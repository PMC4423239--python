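"""1:1 Langmuir mass-transport kinetics: simulation, fitting, competition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiegelstruct import fixtures as fx
from spiegelstruct.spr import (
    KineticModel,
    closed_form_langmuir,
    default_concentration_series,
    fit_kinetics,
    free_ligand_concentration,
    scale_ka,
    simulate_competition,
    simulate_sensorgram,
)


def test_model_invariants():
    m = KineticModel(1e6, 1e-3, 100.0)
    assert m.Kd == pytest.approx(1e-9)
    with pytest.raises(ValueError):
        KineticModel(-1e6, 1e-3, 100.0)


def test_default_series_matches_protocol():
    series = default_concentration_series()
    assert series[0] == pytest.approx(500e-9)
    assert series[1] == pytest.approx(250e-9)
    assert series[-1] == 0.0
    assert len(series) == 15  # fourteen two-fold dilutions plus the blank


def test_zero_concentration_stays_zero(kinetic_model):
    s = simulate_sensorgram(kinetic_model, 0.0)
    assert np.allclose(s.response, 0.0)


def test_saturation_limit_without_dissociation():
    m = KineticModel(1e6, 1e-12, 100.0, 1e9)
    s = simulate_sensorgram(m, 1e-6, t_assoc=2000.0, t_dissoc=10.0)
    assoc = s.response[s.times <= s.t_assoc]
    assert np.all(np.diff(assoc) >= -1e-9)  # monotone approach
    assert assoc[-1] == pytest.approx(100.0, abs=0.5)


def test_response_bounded_and_dissociation_non_increasing(kinetic_model):
    for conc in (500e-9, 31.3e-9, 1.95e-9):
        s = simulate_sensorgram(kinetic_model, conc)
        assert np.all(s.response <= kinetic_model.rmax + 1e-9)
        dissoc = s.response[s.times >= s.t_assoc]
        assert np.all(np.diff(dissoc) <= 1e-9)


def test_transport_free_limit_matches_closed_form(kinetic_model):
    m = KineticModel(kinetic_model.ka, kinetic_model.kd, kinetic_model.rmax, kt=1e12)
    for conc in (500e-9, 62.5e-9, 7.8e-9):
        s = simulate_sensorgram(m, conc, dt=0.5)
        exact = closed_form_langmuir(m, conc, s.times, s.t_assoc)
        assert np.max(np.abs(s.response - exact)) < 0.1  # RU


def test_equilibrium_plateau_matches_langmuir_isotherm():
    m = KineticModel(1e6, 1e-3, 100.0, kt=1e9)
    for conc in (500e-9, 10e-9):
        s = simulate_sensorgram(m, conc, t_assoc=20000.0, t_dissoc=1.0, dt=5.0)
        plateau = s.response[s.times <= s.t_assoc][-1]
        assert plateau == pytest.approx(m.req(conc), rel=0.005)


def test_mass_transport_slows_association(kinetic_model):
    limited = simulate_sensorgram(kinetic_model, 100e-9)
    free = simulate_sensorgram(
        KineticModel(kinetic_model.ka, kinetic_model.kd, kinetic_model.rmax, 1e12), 100e-9
    )
    mid = limited.times <= limited.t_assoc / 2
    assert np.all(limited.response[mid] <= free.response[mid] + 1e-9)


def test_invalid_dt_rejected(kinetic_model):
    with pytest.raises(ValueError):
        simulate_sensorgram(kinetic_model, 1e-9, dt=0.0)


class TestFitting:
    def test_noiseless_recovery_within_one_percent(self, kinetic_model):
        concs = [500e-9, 125e-9, 31.3e-9, 7.8e-9]
        grams = fx.make_sensorgram_set(kinetic_model, concs, noise_sd=0.0, dt=1.0)
        fit = fit_kinetics(grams)
        assert fit.converged
        assert fit.estimates.ka == pytest.approx(kinetic_model.ka, rel=0.01)
        assert fit.estimates.kd == pytest.approx(kinetic_model.kd, rel=0.01)
        assert fit.estimates.rmax == pytest.approx(kinetic_model.rmax, rel=0.01)

    def test_kd_equals_ratio_exactly(self, kinetic_model):
        grams = fx.make_sensorgram_set(kinetic_model, [100e-9, 10e-9], dt=2.0)
        fit = fit_kinetics(grams)
        assert fit.Kd == fit.estimates.kd / fit.estimates.ka

    def test_noisy_recovery_twenty_replicates(self, kinetic_model):
        """sigma = 2 RU additive noise: parameters within 10 % relative."""
        concs = [500e-9, 125e-9, 31.3e-9, 7.8e-9]
        for seed in range(20):
            grams = fx.make_sensorgram_set(kinetic_model, concs, noise_sd=2.0, seed=seed, dt=2.0)
            fit = fit_kinetics(grams)
            assert fit.estimates.ka == pytest.approx(kinetic_model.ka, rel=0.10)
            assert fit.estimates.kd == pytest.approx(kinetic_model.kd, rel=0.10)
            assert fit.Kd == pytest.approx(kinetic_model.Kd, rel=0.10)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    a=st.floats(1e-12, 1e-6),
    b=st.floats(0.0, 1e-5),
    kd=st.floats(1e-12, 1e-6),
)
def test_free_ligand_root_solves_equilibrium(a, b, kd):
    af = free_ligand_concentration(a, b, kd)
    assert 0.0 <= af <= a * (1 + 1e-12) + 1e-20
    # residual of the mass-action quadratic, scaled to its largest term
    residual = af * af + (b - a + kd) * af - kd * a
    scale = max(af * af, abs((b - a + kd) * af), kd * a, 1e-300)
    assert abs(residual) <= 1e-9 * scale


class TestCompetition:
    def test_zero_competitor_fraction_one(self, kinetic_model):
        curve = simulate_competition(kinetic_model, 1e-9, 50e-9, [0.0, 1e-10])
        assert curve.signal_fraction[0] == pytest.approx(1.0, abs=1e-6)

    def test_sequestration_limit(self, kinetic_model):
        curve = simulate_competition(kinetic_model, 1e-10, 1e-9, [0.0, 1e-4])
        assert curve.signal_fraction[-1] < 0.02

    def test_monotone_non_increasing(self, kinetic_model):
        series = np.array([0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6])
        curve = simulate_competition(kinetic_model, 1e-9, 5e-9, series)
        assert np.all(np.diff(curve.signal_fraction) <= 1e-9)

    def test_half_depletion_matches_quadratic_closed_form(self, kinetic_model):
        # at A = Kd, substituting A_free = A/2 into the mass-action
        # quadratic gives B = 3A/2
        kd_sol = 1e-9
        a = kd_sol
        b = 1.5 * a
        af = free_ligand_concentration(a, b, kd_sol)
        assert af == pytest.approx(a / 2, rel=1e-9)

    def test_negative_concentration_rejected(self, kinetic_model):
        with pytest.raises(ValueError):
            simulate_competition(kinetic_model, 1e-9, 1e-9, [-1e-9])


def test_ion_scenario_scales_ka_only(kinetic_model):
    scaled = scale_ka(kinetic_model, 3.0)
    assert scaled.ka == pytest.approx(3e6)
    assert scaled.kd == kinetic_model.kd and scaled.rmax == kinetic_model.rmax
    assert scaled.Kd == pytest.approx(kinetic_model.Kd / 3.0)


def test_sensorgram_set_deterministic(kinetic_model):
    a = fx.make_sensorgram_set(kinetic_model, [100e-9], noise_sd=2.0, seed=5, dt=2.0)
    b = fx.make_sensorgram_set(kinetic_model, [100e-9], noise_sd=2.0, seed=5, dt=2.0)
    assert np.array_equal(a[0].response, b[0].response)
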