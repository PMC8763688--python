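"""Monte-Carlo parameter identification: recovery, determinism, goodness."""

import numpy as np
import pandas as pd
import pytest

import homopbk as h
from homopbk.errors import FitError, ValidationError


def two_param_spec(n_iterations=400, seed=7):
    return h.FitSpec(parameters=(
        h.FitParameter("fraction_unbound", 0.005, 0.05, "log"),
        h.FitParameter("blood_cell_plasma_partition", 5.0, 80.0, "log")),
        n_iterations=n_iterations, seed=seed)


def test_recovery_on_noise_free_data(rat_factory, noise_free_rat_dataset):
    res = h.fit(rat_factory, noise_free_rat_dataset.data, two_param_spec())
    truth = noise_free_rat_dataset.truth
    rel = abs(res.best_params["fraction_unbound"]
              - truth["fraction_unbound"]) / truth["fraction_unbound"]
    assert rel < 0.15
    assert res.loss < 0.05      # noise-free: loss approaches zero


def test_same_seed_identical_result(rat_factory, noise_free_rat_dataset):
    r1 = h.fit(rat_factory, noise_free_rat_dataset.data,
               two_param_spec(n_iterations=50))
    r2 = h.fit(rat_factory, noise_free_rat_dataset.data,
               two_param_spec(n_iterations=50))
    assert r1.best_params == r2.best_params
    assert r1.loss == r2.loss
    assert np.array_equal(r1.trace, r2.trace)


def test_collapsed_bounds_return_that_point(rat_factory,
                                            noise_free_rat_dataset):
    spec = h.FitSpec(parameters=(
        h.FitParameter("fraction_unbound", 0.02, 0.02),),
        n_iterations=5, seed=1)
    res = h.fit(rat_factory, noise_free_rat_dataset.data, spec)
    assert res.best_params["fraction_unbound"] == pytest.approx(0.02)


def test_trace_non_increasing(rat_factory, noise_free_rat_dataset):
    res = h.fit(rat_factory, noise_free_rat_dataset.data,
                two_param_spec(n_iterations=60))
    assert np.all(np.diff(res.trace) <= 0.0)
    assert res.trace[-1] == res.loss


def test_recovery_bias_over_replicates(rat_factory):
    """Median recovered/true Fu over noisy replicates stays near unity."""
    spec = h.FitSpec(parameters=(
        h.FitParameter("fraction_unbound", 0.005, 0.05, "log"),),
        n_iterations=150, seed=0)
    ratios = []
    for rep in range(10):
        ds = h.generate_rat_iv_dataset(doses=(0.5,), noise_cv=0.15,
                                       seed=100 + rep)
        import dataclasses
        res = h.fit(rat_factory, ds.data,
                    dataclasses.replace(spec, seed=rep))
        ratios.append(res.best_params["fraction_unbound"] / 0.014)
    med = float(np.median(ratios))
    assert 0.85 <= med <= 1.18


def test_all_failures_raise_fit_error(noise_free_rat_dataset):
    def broken_factory(params):
        raise RuntimeError("cannot build")
    spec = h.FitSpec(parameters=(h.FitParameter("fraction_unbound", 0.01, 0.02),),
                     n_iterations=3, seed=0)
    with pytest.raises(FitError):
        h.fit(broken_factory, noise_free_rat_dataset.data, spec)


def test_too_few_observations_rejected(rat_factory):
    obs = pd.DataFrame({"time_h": [1.0, 2.0], "conc_ng_ml": [5.0, 3.0]})
    with pytest.raises(ValidationError):
        h.fit(rat_factory, obs, two_param_spec(n_iterations=2))


def test_loq_exclusion(rat_factory, noise_free_rat_dataset):
    data = noise_free_rat_dataset.data
    import dataclasses
    spec = dataclasses.replace(two_param_spec(n_iterations=5),
                               loq=float(data["conc_ng_ml"].max()) * 2)
    with pytest.raises(ValidationError):   # everything below LOQ
        h.fit(rat_factory, data, spec)


class TestGoodnessProfile:
    def test_identical_curves_unit_ratios(self, rat_factory,
                                          noise_free_rat_dataset):
        truth = {"fraction_unbound": 0.014,
                 "blood_cell_plasma_partition": 21.28}
        gp = h.goodness_profile(rat_factory, truth,
                                noise_free_rat_dataset.data)
        assert gp.cmax_ratio == pytest.approx(1.0, rel=1e-6)
        assert gp.auc_ratio == pytest.approx(1.0, rel=1e-6)
        assert gp.acceptable()

    def test_doubled_prediction_ratio_two(self, rat_factory,
                                          noise_free_rat_dataset):
        data = noise_free_rat_dataset.data.copy()
        data["conc_ng_ml"] = data["conc_ng_ml"] / 2.0   # obs halved
        truth = {"fraction_unbound": 0.014,
                 "blood_cell_plasma_partition": 21.28}
        gp = h.goodness_profile(rat_factory, truth, data)
        assert gp.cmax_ratio == pytest.approx(2.0, rel=1e-6)
        assert not gp.acceptable()
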