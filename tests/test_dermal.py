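"""Skin diffusion: discretization, analytic oracles, calibration, coupling."""

import numpy as np
import pytest

import homopbk as h
from homopbk.dermal import (SkinLayerSpec, UptakeSpec, VehicleSpec,
                            build_skin_grid, default_layers)
from homopbk.errors import CalibrationError, RangeError, ValidationError


def test_default_grid_construction(skin_grid):
    assert skin_grid.n_nodes == 120
    assert np.all(np.diff(skin_grid.depths) > 0)
    assert skin_grid.depths[-1] < (20 + 80 + 1200)


def test_single_layer_reduces_to_homogeneous_slab():
    g = build_skin_grid([SkinLayerSpec("stratum_corneum", 100.0, 10, 1.0, 1e-3)],
                        uptake=UptakeSpec(mode="none"), bottom="sink")
    assert g.n_nodes == 10
    assert np.all(g.k == 1.0)
    assert np.all(g.d == 1e-3)


def test_non_positive_k_or_d_rejected():
    with pytest.raises(ValidationError):
        SkinLayerSpec("dermis", 100.0, 10, 0.0, 1e-3)
    with pytest.raises(ValidationError):
        SkinLayerSpec("dermis", 100.0, 10, 1.0, -1e-3)


def test_zero_dose_zero_penetration(skin_grid):
    res = h.simulate_penetration(skin_grid, 0.0, duration=6.0)
    assert np.all(res.q_cumulative == 0.0)


def test_q_monotone_and_bounded(calibrated_grid_5p3):
    res = h.simulate_penetration(calibrated_grid_5p3, 103.0, duration=24.0)
    assert np.all(np.diff(res.q_cumulative) >= -1e-12)
    assert res.q_cumulative[-1] <= 103.0


def test_mass_balance_at_all_times(calibrated_grid_5p3):
    res = h.simulate_penetration(calibrated_grid_5p3, 103.0, duration=24.0)
    total = (res.vehicle_amount + res.surface_pool + res.total_in_skin()
             + res.q_cumulative)
    assert np.all(np.abs(total - 103.0) / 103.0 < 1e-3)


def test_infinite_dose_slab_flux_and_lag_vs_analytic():
    """Constant-donor homogeneous membrane: J_ss = K·D·C_v/h, lag = h²/6D."""
    k_part, d_diff, h_um = 1.0, 1e-3, 200.0
    grid = build_skin_grid(
        [SkinLayerSpec("stratum_corneum", h_um, 40, k_part, d_diff)],
        vehicle=VehicleSpec(volume_per_area=10.0, partition_vs_water=1.0,
                            immobilization_rate=0.0),
        uptake=UptakeSpec(mode="none"), bottom="sink")
    h_cm = h_um * 1e-4
    lag = h_cm ** 2 / (6.0 * d_diff)
    res = h.simulate_penetration(grid, 1.0, duration=10.0 * lag,
                                 donor="infinite", dt=lag / 200.0)
    c_v = 1.0 / (10.0 * 1e-3)    # µg/cm³ in the film
    j_ss = k_part * d_diff * c_v / h_cm
    assert res.flux[-1] == pytest.approx(j_ss, rel=0.02)
    lag_est = res.time[-1] - res.q_cumulative[-1] / res.flux[-1]
    assert lag_est == pytest.approx(lag, rel=0.02)


def test_grid_refinement_convergence(calibrated_grid_5p3):
    mult = calibrated_grid_5p3.calibration["d_sc_multiplier"]
    fine = build_skin_grid(default_layers(80)).with_sc_multipliers(d_mult=mult)
    q40 = h.simulate_penetration(calibrated_grid_5p3, 103.0, 24.0).q_cumulative[-1]
    q80 = h.simulate_penetration(fine, 103.0, 24.0).q_cumulative[-1]
    assert abs(q80 - q40) / q40 < 0.01


def test_q_monotone_in_d_sc(skin_grid):
    qs = []
    for m in (0.5, 1.0, 2.0, 5.0, 20.0):
        g = skin_grid.with_sc_multipliers(d_mult=m)
        qs.append(h.simulate_penetration(g, 103.0, 24.0).q_cumulative[-1])
    assert np.all(np.diff(qs) > 0)


class TestCalibration:
    def test_target_5p3_gives_printed_q(self, calibrated_grid_5p3):
        q = h.simulate_penetration(calibrated_grid_5p3, 103.0, 24.0).q_cumulative[-1]
        assert q == pytest.approx(5.46, abs=0.01)

    def test_target_3p86_gives_about_4(self, skin_grid):
        g = h.calibrate_to_fraction(skin_grid, 103.0, 0.0386)
        q = h.simulate_penetration(g, 103.0, 24.0).q_cumulative[-1]
        assert q == pytest.approx(3.98, abs=0.02)

    def test_half_dose_halves_q(self, calibrated_grid_5p3):
        q_full = h.simulate_penetration(calibrated_grid_5p3, 103.0, 24.0).q_cumulative[-1]
        q_half = h.simulate_penetration(calibrated_grid_5p3, 51.5, 24.0).q_cumulative[-1]
        assert q_half == pytest.approx(q_full / 2.0, rel=1e-9)

    def test_unreachable_target_raises(self, skin_grid):
        with pytest.raises((CalibrationError, RangeError)):
            h.calibrate_to_fraction(skin_grid, 103.0, 0.9999)

    def test_invalid_fraction(self, skin_grid):
        with pytest.raises(RangeError):
            h.calibrate_to_fraction(skin_grid, 103.0, 1.5)


class TestSkinSensitivityScreen:
    def test_sc_parameters_dominate(self, calibrated_grid_5p3):
        df = h.sensitivity_screen_skin(calibrated_grid_5p3, 103.0)
        top_layers = df.iloc[:2]["layer"].tolist()
        assert top_layers == ["stratum_corneum", "stratum_corneum"]

    def test_d_dermis_less_influential_than_d_sc(self, calibrated_grid_5p3):
        df = h.sensitivity_screen_skin(calibrated_grid_5p3, 103.0)
        s = {(r.layer, r.parameter): abs(r.S) for r in df.itertuples()}
        assert s[("dermis", "D")] < s[("stratum_corneum", "D")]

    def test_zero_perturbation_zero_sensitivity(self, skin_grid):
        df = h.sensitivity_screen_skin(skin_grid, 103.0, perturbation=0.0)
        assert (df["S"] == 0.0).all()


class TestSystemicCoupling:
    def test_zero_uptake_no_plasma(self, human_model):
        g = build_skin_grid(uptake=UptakeSpec(mode="none"))
        model = h.couple_to_systemic(human_model, g, 1000.0)
        reg = h.DoseRegimen(route="dermal", dose=103.0, times=(0.0,),
                            application_area=1000.0, product_fraction=0.1)
        res = h.simulate(model, reg, 24.0)
        assert np.all(res.plasma_concentration < 1e-12)

    def test_systemic_input_equals_q_times_area(self, human_model,
                                                calibrated_grid_5p3):
        area = 17500.0
        model = h.couple_to_systemic(human_model, calibrated_grid_5p3, area)
        reg = h.DoseRegimen(route="dermal", dose=103.0, times=(0.0,),
                            application_area=area, product_fraction=0.1)
        res = h.simulate(model, reg, 24.0)
        q24 = h.simulate_penetration(calibrated_grid_5p3, 103.0,
                                     24.0).q_cumulative[-1]
        assert res.cumulative_absorbed[-1] == pytest.approx(q24 * area,
                                                            rel=0.005)

    def test_area_exceeding_body_surface_rejected(self, human_model,
                                                  skin_grid):
        with pytest.raises(ValidationError):
            h.couple_to_systemic(human_model, skin_grid, 50000.0)

    def test_double_coupling_rejected(self, human_model, skin_grid):
        m = h.couple_to_systemic(human_model, skin_grid, 1000.0)
        from homopbk.errors import ConstructionError
        with pytest.raises(ConstructionError):
            h.couple_to_systemic(m, skin_grid, 1000.0)
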