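import numpy as np
import pytest

import paddyopt as po


@pytest.fixture(scope="session")
def coeffs():
    return po.load_coefficients()


@pytest.fixture(scope="session")
def toy_cohort():
    return po.make_toy_fixture()


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Default-conditions cohort with mean yields calibrated to the published
    method averages; shared across tests that only read it."""
    cfg = po.calibrate_mean_yields()
    return cfg, po.generate_cohort(cfg)


@pytest.fixture(scope="session")
def calibrated_benefits(calibrated_cohort, coeffs):
    _, cohort = calibrated_cohort
    return po.benefit_table(cohort, coeffs)


@pytest.fixture()
def mt_record():
    """The published MT mean input vector as a single record."""
    return {
        "method": "MT", "n_rate": 136.0, "p_rate": 78.6, "k_rate": 143.5,
        "seed_rate": 20.5, "herbicide": 0.0, "pesticide": 0.0,
        "labor_hours": 0.0, "machine_hours": 0.0, "grain_yield": 10000.0,
        "straw_yield": np.nan,
    }
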