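import numpy as np
import pytest

from fishrdm import economics, exploratory_modeling as em
from fishrdm import population_model as pm
from fishrdm import sr_models as sr
from fishrdm import synthetic_data as sd


@pytest.fixture(scope="session")
def biology():
    return sd.generate_biology(6, seed=1)


@pytest.fixture(scope="session")
def ricker_truth():
    params, bounds = sr.table1_midpoint_params("env_ricker")
    return params, bounds


@pytest.fixture(scope="session")
def bh_truth():
    params, bounds = sr.table1_midpoint_params("env_beverton_holt")
    return params, bounds


@pytest.fixture(scope="session")
def bounds_by_form(ricker_truth, bh_truth):
    return {"env_ricker": ricker_truth[1], "env_beverton_holt": bh_truth[1]}


@pytest.fixture(scope="session")
def sst_bank():
    return {s: sd.generate_sst_projection(s, seed=2) for s in sd.SCENARIOS}


@pytest.fixture(scope="session")
def econ(biology):
    hindcast = sd.generate_hindcast_catches(biology, seed=3)
    base = economics.EconParams(price_table=sd.make_price_table(),
                                cost_scale=100.0)
    return economics.calibrate_reference(hindcast, biology, base,
                                         target_mean_profit=50e6)


@pytest.fixture(scope="session")
def refpts():
    return pm.ReferencePoints()


@pytest.fixture(scope="session")
def small_ensemble(biology, bounds_by_form, sst_bank, econ, refpts):
    """A 2 forms x 8 schemes x 6 policies = 96-run ensemble."""
    design = em.default_design(bounds_by_form, n_schemes=8, n_policies=6,
                               seed=0)
    return em.run_experiments(design, biology, econ, refpts, sst_bank)


def constant_sst(value: float, scenario: str = "moderate",
                 start: int = 2030, end: int = 2600) -> sd.SSTTrajectory:
    years = np.arange(start, end + 1)
    return sd.SSTTrajectory(scenario_id=scenario, years=years,
                            sst=np.full(len(years), value))
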