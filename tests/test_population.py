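"""Virtual populations, uncertainty sampling and CI(5–95)% summaries."""

import numpy as np
import pytest

import homopbk as h
from homopbk.distribution import build_partition_set
from homopbk.errors import ValidationError


def rat_builder(substance):
    clearance = h.ClearanceSpec(mode="total_plasma", total_plasma_clearance=6.0)

    def build(individual, draws):
        sub = substance
        overrides = {k: float(v) for k, v in draws.items()
                     if hasattr(substance, k)}
        if overrides:
            sub = substance.replace(**overrides)
        return h.build_model(individual, sub,
                             build_partition_set(sub, individual), clearance)

    return build


def test_population_within_stated_ranges():
    pop = h.generate_population(h.PopulationSpec(species="rat",
                                                 n_individuals=100, seed=42))
    bws = [i.body_weight for i in pop]
    assert len(pop) == 100
    assert min(bws) >= 0.185 and max(bws) <= 0.275


def test_human_population_age_and_bw():
    pop = h.generate_population(h.PopulationSpec(species="human",
                                                 n_individuals=50, seed=2))
    assert all(16.0 <= i.age <= 70.0 for i in pop)
    assert all(45.0 <= i.body_weight <= 100.0 for i in pop)


def test_same_seed_identical_population():
    spec = h.PopulationSpec(species="rat", n_individuals=20, seed=9)
    p1 = h.generate_population(spec)
    p2 = h.generate_population(spec)
    assert [i.body_weight for i in p1] == [i.body_weight for i in p2]


def test_degenerate_range_reproduces_reference():
    spec = h.PopulationSpec(species="rat", n_individuals=2,
                            rat_bw_range=(0.23, 0.23), seed=0)
    ref = h.build_individual("rat")
    for ind in h.generate_population(spec):
        assert ind.body_weight == pytest.approx(ref.body_weight)
        assert ind.organ("liver").volume == pytest.approx(
            ref.organ("liver").volume)


class TestUncertaintySampling:
    def test_zero_sd_constant(self):
        spec = {"fraction_unbound": h.UncertainParameter(0.02, 0.0)}
        draws = h.sample_uncertain_parameters(spec, 10, seed=1)
        assert (draws["fraction_unbound"] == 0.02).all()

    def test_sample_mean_close_to_stated(self):
        # Fu 2 ± 0.2%: with 10^4 draws the mean lands within 2 %
        spec = {"fu": h.UncertainParameter(0.02, 0.002, 0.0, 1.0)}
        draws = h.sample_uncertain_parameters(spec, 10_000, seed=3)
        assert draws["fu"].mean() == pytest.approx(0.02, rel=0.02)

    def test_truncation_respected(self):
        spec = {"p": h.UncertainParameter(1.0, 5.0, 0.5, 1.5)}
        draws = h.sample_uncertain_parameters(spec, 500, seed=4)
        assert draws["p"].between(0.5, 1.5).all()

    def test_bounds_excluding_mean_rejected(self):
        with pytest.raises(ValidationError):
            h.UncertainParameter(0.02, 0.002, 0.05, 0.10)


class TestPopulationSimulate:
    def test_homogeneous_population_degenerate_ci(self, substance):
        spec = h.PopulationSpec(species="rat", n_individuals=3,
                                rat_bw_range=(0.23, 0.23), seed=0)
        pop = h.generate_population(spec)
        res = h.population_simulate(rat_builder(substance),
                                    h.DoseRegimen(route="iv_bolus", dose=0.5),
                                    pop, t_end=8.0)
        s = res.summary["auc_0_24"]
        assert s["ci5"] == pytest.approx(s["mean"])
        assert s["ci95"] == pytest.approx(s["mean"])

    def test_ci_ordering_and_growth_with_uncertainty(self, substance):
        spec = h.PopulationSpec(species="rat", n_individuals=30, seed=1)
        pop = h.generate_population(spec)
        reg = h.DoseRegimen(route="iv_bolus", dose=0.5)
        widths = []
        for sd in (0.0, 0.001, 0.002):
            draws = h.sample_uncertain_parameters(
                {"fraction_unbound": h.UncertainParameter(0.014, sd,
                                                          1e-4, 1.0)},
                len(pop), seed=5)
            res = h.population_simulate(rat_builder(substance), reg, pop,
                                        parameter_draws=draws, t_end=8.0,
                                        window=(0.0, 8.0))
            s = res.summary["auc_0_24"]
            assert s["ci5"] <= s["mean"] <= s["ci95"]
            widths.append(s["ci95"] - s["ci5"])
        assert widths[0] < widths[1] < widths[2]

    def test_percentile_definition_recorded(self, substance):
        spec = h.PopulationSpec(species="rat", n_individuals=3, seed=1)
        pop = h.generate_population(spec)
        res = h.population_simulate(rat_builder(substance),
                                    h.DoseRegimen(route="iv_bolus", dose=0.5),
                                    pop, t_end=4.0)
        assert "type 7" in res.percentile_definition

    def test_misaligned_draws_rejected(self, substance):
        pop = h.generate_population(
            h.PopulationSpec(species="rat", n_individuals=3, seed=1))
        draws = h.sample_uncertain_parameters(
            {"fraction_unbound": h.UncertainParameter(0.014, 0.001)}, 5, 1)
        with pytest.raises(ValidationError):
            h.population_simulate(rat_builder(h.packaged_substance()),
                                  h.DoseRegimen(route="iv_bolus", dose=0.5),
                                  pop, parameter_draws=draws)


def test_sampling_stability_n100_vs_n1000(substance):
    """CI bounds move by < 10 % when the population grows 100 -> 1000."""
    reg = h.DoseRegimen(route="iv_bolus", dose=0.5)
    build = rat_builder(substance)
    bounds = {}
    for n in (100, 1000):
        pop = h.generate_population(
            h.PopulationSpec(species="rat", n_individuals=n, seed=17))
        res = h.population_simulate(build, reg, pop, t_end=4.0,
                                    window=(0.0, 4.0))
        bounds[n] = res.summary["auc_0_24"]
    for key in ("ci5", "ci95"):
        rel = abs(bounds[1000][key] - bounds[100][key]) / bounds[100][key]
        assert rel < 0.10
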