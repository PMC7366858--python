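import logging

import pytest

from mdenm import (build_system, compute_hessian, compute_modes, minimize)
from mdenm.campaign import CampaignSpec, run_state

logging.getLogger("mdenm").setLevel(logging.ERROR)

#: master seeds for the stochastic sampling campaigns (fixed up front)
CAMPAIGN_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def gdp_build():
    return build_system("GDP", seed=1)


@pytest.fixture(scope="session")
def gtp_build():
    return build_system("GTP", seed=1)


@pytest.fixture(scope="session")
def gdp_minimized(gdp_build):
    topo, conf = gdp_build
    return topo, minimize(topo, conf)


@pytest.fixture(scope="session")
def gdp_modes(gdp_minimized):
    topo, mini = gdp_minimized
    H = compute_hessian(topo, mini)
    return topo, mini, compute_modes(H, topo, 10, reference=mini)


@pytest.fixture(scope="session")
def campaign_results():
    """Default-parameter MDeNM + plain-MD campaigns, both states,
    three master seeds (the stochastic-comparison dataset)."""
    results = {}
    for seed in CAMPAIGN_SEEDS:
        spec = CampaignSpec(seed=seed, n_orientations=1,
                            equilibration_steps=25000)
        for state in ("GDP", "GTP"):
            results[(seed, state)] = run_state(spec, state)
    return results
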