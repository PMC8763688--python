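import numpy as np
import pytest

import homopbk as h
from homopbk.distribution import build_partition_set


@pytest.fixture(scope="session")
def rat():
    return h.build_individual("rat")


@pytest.fixture(scope="session")
def human():
    return h.build_individual("human")


@pytest.fixture(scope="session")
def substance():
    return h.packaged_substance("homosalate_optimized")


@pytest.fixture(scope="session")
def rat_model():
    return h.rat_reference_model()


@pytest.fixture(scope="session")
def human_model():
    return h.human_reference_model()


@pytest.fixture(scope="session")
def skin_grid():
    return h.build_skin_grid()


@pytest.fixture(scope="session")
def calibrated_grid_5p3(skin_grid):
    return h.calibrate_to_fraction(skin_grid, 103.0, 0.053)


@pytest.fixture(scope="session")
def rat_factory(rat, substance):
    """Parameterizable rat model builder for identification tests."""
    clearance = h.ClearanceSpec(mode="total_plasma", total_plasma_clearance=6.0)

    def factory(params):
        sub = substance.replace(**params)
        return h.build_model(rat, sub, build_partition_set(sub, rat), clearance)

    return factory


@pytest.fixture(scope="session")
def noise_free_rat_dataset():
    return h.generate_rat_iv_dataset(doses=(0.5,), noise_cv=0.0, seed=11)


def one_compartment_model(volume_ml: float, k_per_h: float) -> h.PBKModel:
    """Degenerate single-compartment configuration for closed-form checks.

    A hand-wired PBKModel whose only mass-carrying state is venous plasma
    with first-order elimination k; C(t) = (D/V)·e^(−kt) exactly.
    """
    ind = h.build_individual("rat")
    # venous plasma volume is venous_blood × (1 − hct); pick blood volume so
    # the plasma volume equals the requested one-compartment volume
    import dataclasses
    # bump body weight so the enlarged blood pool passes the volume check
    ind = dataclasses.replace(ind, body_weight=1.0,
                              venous_blood_volume=volume_ml / (1 - ind.hematocrit))
    index = {"venous.pl": 0, "cum_eliminated": 1, "cum_absorbed": 2}
    a = np.zeros((3, 3))
    a[0, 0] = -k_per_h
    a[1, 0] = k_per_h
    return h.PBKModel(
        individual=ind, substance=h.packaged_substance(),
        partition_set=h.build_partition_set(h.packaged_substance(), ind),
        clearance_spec=h.ClearanceSpec(mode="total_plasma",
                                       total_plasma_clearance=0.0),
        oral_spec=None, index=index, matrix=a, n_dynamic=1,
    )
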