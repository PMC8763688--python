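"""Local sensitivity statistic and WHO classification bands."""

import numpy as np
import pytest

import homopbk as h
from homopbk.errors import ValidationError


@pytest.fixture(scope="module")
def iv_regimen():
    return h.DoseRegimen(route="iv_bolus", dose=0.5)


def test_s_equals_one_for_dose_proportional_endpoint(rat_model, iv_regimen):
    r = h.local_sensitivity(rat_model, iv_regimen, "dose", endpoint="cmax")
    assert r.sensitivity == pytest.approx(1.0, abs=1e-6)
    # proportionality holds for every step size
    r2 = h.local_sensitivity(rat_model, iv_regimen, "dose", endpoint="cmax",
                             n_steps=2, step_fraction=0.3)
    assert r2.sensitivity == pytest.approx(1.0, abs=1e-6)


def test_s_minus_one_for_auc_vs_clearance(rat_model, iv_regimen):
    """AUC(0–∞) = D/CL: the relative-sensitivity statistic converges to −1;
    at the default ±10% ladder it carries the exact −1/(1−δ²) step bias."""
    small = h.local_sensitivity(rat_model, iv_regimen,
                                "clearance.total_plasma_clearance",
                                endpoint="auc_inf", step_fraction=0.02)
    assert small.sensitivity == pytest.approx(-1.0, abs=0.01)
    default = h.local_sensitivity(rat_model, iv_regimen,
                                  "clearance.total_plasma_clearance",
                                  endpoint="auc_inf")
    expected_bias = -np.mean([1.0 / (1.0 - (0.1 * k) ** 2) for k in range(1, 6)])
    assert default.sensitivity == pytest.approx(expected_bias, rel=1e-6)


def test_inert_parameter_gives_zero(iv_regimen):
    model = h.rat_reference_model(with_oral=True)
    r = h.local_sensitivity(model, iv_regimen, "oral.intestinal_permeability",
                            endpoint="auc_inf")
    assert r.sensitivity == pytest.approx(0.0, abs=1e-9)
    assert r.classification == "negligible"


def test_fu_negatively_impacts_exposure(rat_model, iv_regimen):
    r = h.local_sensitivity(rat_model, iv_regimen,
                            "substance.fraction_unbound",
                            endpoint="auc_0_24", t_end=8.0, n_steps=2)
    assert r.sensitivity < 0


@pytest.mark.parametrize("s,expected", [
    (-0.77, "high"), (0.5, "high"), (0.2, "medium"), (0.49, "medium"),
    (0.1, "low"), (0.19, "low"), (0.09, "negligible"), (0.0, "negligible"),
])
def test_who_classification_bands(s, expected):
    assert h.classify(s) == expected


def test_classify_rejects_non_finite():
    with pytest.raises(ValidationError):
        h.classify(float("nan"))


class TestReport:
    def test_sorted_and_filtered(self, rat_model, iv_regimen):
        rep = h.sensitivity_report(
            rat_model, iv_regimen,
            ["dose", "clearance.total_plasma_clearance"],
            endpoint="auc_inf", n_steps=2)
        abs_s = rep.table["S"].abs().to_numpy()
        assert np.all(np.diff(abs_s) <= 1e-12)
        assert set(rep.table["parameter"]) == {
            "dose", "clearance.total_plasma_clearance"}

    def test_all_inert_list_empty_default_view(self, iv_regimen):
        model = h.rat_reference_model(with_oral=True)
        rep = h.sensitivity_report(model, iv_regimen,
                                   ["oral.intestinal_permeability"],
                                   endpoint="auc_inf", n_steps=2)
        assert rep.significant.empty
        assert len(rep.table) == 1    # raw output retained

    def test_duplicate_parameters_rejected(self, rat_model, iv_regimen):
        with pytest.raises(ValidationError):
            h.sensitivity_report(rat_model, iv_regimen, ["dose", "dose"])

    def test_empty_parameter_list_rejected(self, rat_model, iv_regimen):
        with pytest.raises(ValidationError):
            h.sensitivity_report(rat_model, iv_regimen, [])


def test_invalid_steps_skipped_with_log(rat_model, iv_regimen, caplog):
    # Fu = 0.014: +k·10% steps stay valid, but scaling far above 1 would not;
    # use a 5-step ladder on a parameter near its bound to exercise skipping
    import dataclasses
    sub = rat_model.substance.replace(fraction_unbound=0.9)
    from homopbk.distribution import build_partition_set
    model = h.build_model(rat_model.individual, sub,
                          build_partition_set(sub, rat_model.individual),
                          rat_model.clearance_spec)
    with caplog.at_level("WARNING", logger="homopbk.sensitivity"):
        r = h.local_sensitivity(model, iv_regimen,
                                "substance.fraction_unbound",
                                endpoint="auc_0_24", t_end=4.0, n_steps=3)
    # +30% would push Fu to 1.17 > 1 -> that step must be skipped, not fatal
    assert any("skipping" in rec.message for rec in caplog.records)
    assert np.isfinite(r.sensitivity)
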