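"""Endpoint extraction, dose linearity and margin of internal exposure."""

import numpy as np
import pytest

import homopbk as h
from homopbk.errors import RangeError, ValidationError
from homopbk.metrics import terminal_slope
from homopbk.pbk import SimulationResult


def curve_result(time, conc):
    return SimulationResult(
        time=np.asarray(time, dtype=float),
        plasma_concentration=np.asarray(conc, dtype=float),
        amounts={}, cumulative_eliminated=np.zeros(len(time)),
        cumulative_absorbed=np.zeros(len(time)), dose_administered=0.0,
    )


def test_one_compartment_closed_form_metrics():
    t = np.arange(0.0, 72.0 + 1e-9, 0.1)
    res = curve_result(t, 100.0 * np.exp(-0.1 * t))
    m = h.compute_metrics(res, window=(0.0, 24.0))
    assert m.cmax == pytest.approx(100.0)
    assert m.tmax == 0.0
    assert m.auc_inf == pytest.approx(1000.0, rel=0.005)
    analytic_24 = 100.0 / 0.1 * (1 - np.exp(-0.1 * 24))
    assert m.auc_0_24 == pytest.approx(analytic_24, rel=0.005)


def test_constant_curve_auc():
    t = np.linspace(0, 24, 25)
    m = h.compute_metrics(curve_result(t, np.full(25, 7.0)),
                          window=(0.0, 24.0))
    assert m.auc_0_24 == pytest.approx(24 * 7.0)


def test_auc_additivity_on_shared_grid():
    rng = np.random.default_rng(5)
    t = np.linspace(0, 48, 97)
    c = rng.uniform(1.0, 10.0, len(t))
    a = h.window_auc(t, c, (0.0, 20.0))
    b = h.window_auc(t, c, (20.0, 48.0))
    total = h.window_auc(t, c, (0.0, 48.0))
    assert a + b == pytest.approx(total, rel=1e-12)


def test_tmax_tie_breaks_to_earliest():
    t = np.linspace(0, 10, 11)
    c = np.array([0, 5, 9, 9, 9, 7, 5, 3, 2, 1, 0.5])
    m = h.compute_metrics(curve_result(t, c), window=(0.0, 10.0))
    assert m.tmax == 2.0
    assert m.cmax >= c.max()


def test_rising_terminal_phase_refuses_extrapolation():
    t = np.linspace(0, 24, 49)
    m = h.compute_metrics(curve_result(t, 1.0 + t), window=(0.0, 24.0))
    assert m.auc_inf is None
    assert m.auc_inf_reason    # refusal carries an explanation
    # a curve that peaks, declines, then rises near the end also refuses
    # (terminal log-linear slope is non-negative)
    c = np.concatenate([np.linspace(1, 10, 5),        # rise to peak
                        np.linspace(9.5, 2.0, 24),    # decline
                        np.linspace(2.1, 6.0, 20)])   # terminal rise
    m2 = h.compute_metrics(curve_result(t, c), window=(0.0, 24.0))
    assert m2.auc_inf is None and "declin" in m2.auc_inf_reason


def test_terminal_slope_recovers_k():
    t = np.linspace(0, 48, 97)
    lam, reason = terminal_slope(t, 50 * np.exp(-0.25 * t))
    assert reason is None
    assert lam == pytest.approx(0.25, rel=1e-6)


def test_window_outside_span_rejected():
    t = np.linspace(0, 10, 11)
    with pytest.raises(ValidationError):
        h.window_auc(t, np.ones(11), (0.0, 24.0))


class TestDoseLinearity:
    @staticmethod
    def metrics_for(cmax, auc):
        return h.PKMetrics(cmax=cmax, tmax=1.0, auc_0_24=auc)

    def test_exactly_proportional_spread_zero(self):
        data = [(d, self.metrics_for(10 * d, 100 * d)) for d in (60, 120, 300, 750)]
        r = h.dose_linearity(data)
        assert r.max_proportionality_error == pytest.approx(0.0, abs=1e-12)
        assert r.slope_cmax == pytest.approx(10.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            h.dose_linearity([(60.0, self.metrics_for(1, 1))])

    def test_zero_dose_rejected(self):
        with pytest.raises(RangeError):
            h.dose_linearity([(0.0, self.metrics_for(1, 1)),
                              (1.0, self.metrics_for(1, 1))])


class TestMoIE:
    def test_pass(self):
        r = h.compute_moie(1000.0, 10.0)
        assert r.ratio == pytest.approx(100.0) and r.passes

    def test_fail_below_25(self):
        r = h.compute_moie(100.0, 10.0)
        assert r.ratio == pytest.approx(10.0) and not r.passes

    def test_threshold_override(self):
        r = h.compute_moie(500.0, 10.0, threshold=100.0)
        assert r.ratio == pytest.approx(50.0) and not r.passes

    def test_kind_mismatch(self):
        with pytest.raises(ValidationError):
            h.compute_moie(1.0, 1.0, pod_kind="auc_0_24", human_kind="cmax")

    def test_non_positive_rejected(self):
        with pytest.raises(RangeError):
            h.compute_moie(0.0, 1.0)


def test_accumulation_ratio_constant_curve():
    t = np.linspace(0, 96, 200)
    r = h.accumulation_ratio(curve_result(t, np.full(len(t), 3.0)))
    assert r == pytest.approx(1.0)
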