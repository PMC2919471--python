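import numpy as np
import pytest

from bcdgeom import simulate as sim
from bcdgeom import synthetic as syn
from bcdgeom import pipeline as pl


@pytest.fixture(scope="session")
def noiseless_spec():
    return syn.SyntheticCohortSpec(
        n_embryos=4, seed=7, amplitude_cv=0.0, window_cv_D=0.0, window_cv_V=0.0,
        hb_noise_sd=0.0, shape_sd=(0.0, 0.0, 0.0, 0.0), hb_amplitude_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return syn.generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def wt_cohort():
    """One wild-type-calibrated cohort at the default study conditions."""
    return syn.generate_cohort(syn.SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def wt_analysis(wt_cohort):
    return pl.analyze_cohort([e.traces for e in wt_cohort])


@pytest.fixture(scope="session")
def sim_readout():
    """Full default simulation (published parameters, grid 5 um, dt 0.5 s)."""
    params = sim.SimParams()
    state, audit = sim.run_simulation(params)
    traces = sim.extract_simulated_profiles(state, params)
    return params, state, audit, traces
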