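import logging
import warnings

import numpy as np
import pytest

import ecocycles as ec

# Mixed-model refits on random data emit convergence chatter that is not
# informative at test sizes; keep the log quiet but let errors through.
logging.getLogger("ecocycles").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def params() -> ec.ModelParams:
    return ec.ModelParams()


@pytest.fixture(scope="session")
def su() -> ec.SuParams:
    return ec.SuParams()


@pytest.fixture()
def calibrated_state(params) -> ec.PopState:
    return ec.default_initial_state(params)


@pytest.fixture(scope="session")
def longterm_tables() -> ec.ExperimentTables:
    """One synthetic long-term experiment at default settings, shared."""
    return ec.generate_experiment(ec.ExperimentConfig(seed=101))


@pytest.fixture(scope="session")
def stop_tables() -> ec.ExperimentTables:
    """One synthetic stop-selection experiment (13 populations, 31 gens)."""
    return ec.emulate_stop_selection(
        ec.ExperimentConfig(n_populations=13, n_generations=31, seed=202)
    )


def cycling_of(series: np.ndarray, burn_in: int = 3) -> bool:
    """Shared helper: burn-in, detrend, ACF, oscillatory-decay classifier."""
    detrended = ec.detrend_series(series, burn_in=burn_in)
    return bool(ec.classify_cycling(ec.autocorrelation(detrended)).cycling)
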