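import warnings

import pytest

import voihealth as vh

# Worked example: endpoint prior mean 0.10 (SE 0.04); the programme averts
# 1000/2000/3000 DALYs at endpoint 0.04/0.10/0.19, costs a constant
# US$450,000, and the health opportunity cost is US$300/DALY.
WORKED_DALYS = [(0.04, 1000.0), (0.10, 2000.0), (0.19, 3000.0)]
WORKED_COSTS = [(0.04, 450_000.0), (0.10, 450_000.0), (0.19, 450_000.0)]
LAMBDA = 300.0


@pytest.fixture(scope="session")
def worked_prior():
    return vh.fit_prior(
        vh.PriorSpec("beta", 0.10, 0.04, quantiles=((0.025, 0.04), (0.975, 0.19)))
    )


@pytest.fixture(scope="session")
def worked_net():
    return vh.build_net_curve(
        vh.fit_curve(WORKED_DALYS), vh.fit_curve(WORKED_COSTS), LAMBDA
    )


@pytest.fixture(scope="session")
def worked_result(worked_prior):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # elicited range narrower than the prior
        return vh.analyse_scenario(worked_prior, WORKED_DALYS, WORKED_COSTS, LAMBDA)


def run_generated(seed, **kwargs):
    """Generate and analyse one random scenario, silencing extrapolation warnings."""
    cfg = vh.generate_random_scenario(seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vh.run_scenario(cfg)
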