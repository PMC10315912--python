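"""Session-scoped fixtures: the synthetic world, its calibration, and runs.

The expensive objects (target generation, the least-squares fit, the
tight-tolerance baseline trajectory, and individual scenario runs) are built
once per session and shared; scenario runs are cached on demand.
"""

import numpy as np
import pytest

from t2dmsim import calibrate, interventions, model, outcomes, synthetic


@pytest.fixture(scope="session")
def config():
    return synthetic.BaselineConfig()


@pytest.fixture(scope="session")
def truth(config):
    """(params, initial state, trajectory) of the synthetic ground-truth world."""
    return synthetic.generate_truth(config)


@pytest.fixture(scope="session")
def targets(config, truth):
    _, _, traj = truth
    years = list(range(config.start_year, config.end_year + 1))
    return synthetic._tabulate(traj, years)


@pytest.fixture(scope="session")
def fit_result(targets):
    return calibrate.fit_parameters(targets)


@pytest.fixture(scope="session")
def fitted_params(fit_result):
    return fit_result.params


@pytest.fixture(scope="session")
def initial_state(targets):
    return synthetic.initial_state_from_targets(targets)


@pytest.fixture(scope="session")
def baseline(initial_state, fitted_params):
    return model.simulate(initial_state, fitted_params, (), 2021.0, 2051.0)


@pytest.fixture(scope="session")
def library():
    return interventions.load_scenario_library()


@pytest.fixture(scope="session")
def scenario_runs(fitted_params, targets, baseline, library):
    """Cached scenario runner: ``scenario_runs(name) -> ScenarioResult``."""
    cache = {}

    def get(name: str):
        if name not in cache:
            cache[name] = outcomes.run_scenario(name, fitted_params, targets,
                                                library, baseline=baseline)
        return cache[name]

    return get


@pytest.fixture()
def toy_params():
    """Small closed-system parameter set for engine-level tests."""
    p = model.NaturalHistoryParams(
        lam_a=np.array([-4.0, -4.0]), lam_b=np.zeros(2), lam_c=np.zeros(2),
        mu=np.zeros((model.N_SEX, model.N_AGE)),
        entry_rate0=np.zeros(2), kappa_t2dm=1.0,
        alpha_obese=0.03, omega_obese=0.02,
        alpha_inactive=0.08, omega_inactive=0.10,
        alpha_smoker=0.01, omega_smoker=0.03,
    )
    return p


@pytest.fixture()
def toy_state():
    """A populated state concentrated in a few bands and profiles."""
    st = model.ModelState.zeros(1)
    st.counts[0, 0, 0, 0, 0] = 1000.0
    st.counts[0, 1, 1, 0, 0] = 800.0
    st.counts[1, 0, 3, 0, 0] = 600.0
    st.counts[1, 5, 1, 1, 0] = 50.0
    return st
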