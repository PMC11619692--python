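"""Shared fixtures: reduced-scale study runs reused across test modules.

The fixtures run real simulate-fit-assess pipelines at reduced MCMC lengths
and replicate counts so the whole suite stays desk-scale; the acceptance
tests use the study's full MCMC settings.
"""

import numpy as np
import pytest
from hypothesis import settings

import lcmgof as m

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Reduced sampler settings for property-style checks (not the study protocol).
REDUCED = m.McmcSettings(n_chains=3, n_burnin=1500, n_iter=3000)


@pytest.fixture(scope="session")
def null_run():
    """Correctly specified case: data generated *without* dependence, fitted
    with the conditional-independence model. 60 replicates at n_obs = 500.

    Used for CrI coverage (should be ~95% per parameter) and for the null
    calibration of the pairwise lack-of-fit flags (~5% or below).
    """
    scenario = m.ScenarioConfig(0.3, (0.9, 0.8, 0.9, 0.85), (0.9, 0.85, 0.9, 0.8), 0.0, 500)
    frame = m.run_scenario(scenario, 60, mcmc=REDUCED, root_seed=42, scen_index=0)
    return scenario, frame


@pytest.fixture(scope="session")
def llhh_fit():
    """One LLHH-LLHH data set (the scenario where the tools work as intended)
    fitted at reduced settings; reused by assessment and plotting tests."""
    scenario = m.scenario_from_codes("LLHH", "LLHH", prevalence=0.5, omega=0.5, n_obs=2000)
    dataset = m.simulate_dataset(scenario, 7)
    fit = m.gibbs_fit(dataset, REDUCED, rng=8)
    return scenario, dataset, fit
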