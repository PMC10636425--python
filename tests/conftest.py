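import datetime as dt
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

import scr_camtrap as sc
from scr_camtrap import synthetic_data as syn
from scr_camtrap.types import CaptureHistory


def make_history(y, usage, trap_xy, period=None) -> CaptureHistory:
    """Capture history straight from arrays, for hand fixtures."""
    y = np.asarray(y)
    n, J, K = y.shape
    return CaptureHistory(
        individuals=[f"ind{i}" for i in range(n)],
        sites=[f"site{j}" for j in range(J)],
        K=K,
        y=y,
        usage=np.asarray(usage),
        trap_xy=np.asarray(trap_xy, dtype=float),
        survey_period=period,
    )


@pytest.fixture(scope="session")
def demo_run():
    """One reduced survey simulated and analysed end to end (shared)."""
    sim = syn.demo_config()
    data = syn.simulate_survey(sim, seed=11)
    cfg = syn.survey_config_for(
        sim, mcmc=sc.MCMCConfig(n_iter=2000, burn_in=500), seed=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sc.run_analysis(cfg, data.traps, data.detections)
    return sim, data, result


@pytest.fixture(scope="session")
def standard_run():
    """Denser, well-informed scenario for sampler behaviour checks."""
    sim = syn.standard_scenario()
    data = syn.simulate_survey(sim, seed=3)
    cfg = syn.survey_config_for(
        sim, mcmc=sc.MCMCConfig(n_iter=1500, burn_in=500), seed=3
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sc.run_analysis(cfg, data.traps, data.detections)
    return sim, data, result
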