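import copy
import dataclasses

import numpy as np
import pytest

from normdev.atlas import load_atlas
from normdev.model import HierarchicalNormativeModel
from normdev.simulate import CohortSimulator, GeneratorConfig


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def small_sim():
    """Moderate-size simulator shared across tests (read-only)."""
    return CohortSimulator(GeneratorConfig(seed=7, n_reference=800, n_sites=6))


@pytest.fixture(scope="session")
def _fitted_base(small_sim):
    est = HierarchicalNormativeModel()
    est.fit(*small_sim.reference())
    return est


@pytest.fixture()
def fitted(_fitted_base):
    """Fresh copy of the fitted reference model (mutable per test)."""
    return copy.deepcopy(_fitted_base)


@pytest.fixture(scope="session")
def clinical_scores(_fitted_base, small_sim):
    """Deviation z-scores of the simulated clinical cohort."""
    est = copy.deepcopy(_fitted_base)
    est.adapt(*small_sim.adaptation())
    cohort, thickness = small_sim.clinical()
    res = est.deviation_scores(cohort.set_index("subject_id"), thickness)
    return cohort, res


def zeroed_config(**overrides) -> GeneratorConfig:
    """Config with covariate, site and atrophy effects switched off."""
    cfg = GeneratorConfig(
        age_slope_range=(0.0, 0.0), sex_effect_range=(0.0, 0.0),
        site_intercept_sd=0.0, site_log_scale_sd=0.0,
    )
    cfg.atrophy = dataclasses.replace(cfg.atrophy, core_penetrance=0.0,
                                      idiosyncratic_rate=0.0)
    return dataclasses.replace(cfg, **overrides)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
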