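import numpy as np
import pytest

import ceraflux as cf


@pytest.fixture(scope="session")
def model():
    return cf.build_ceramide_network()


@pytest.fixture(scope="session")
def baseline(model):
    return cf.default_baseline(model)


@pytest.fixture(scope="session")
def baseline_activities(model, baseline):
    return cf.solve_baseline_steady_state(model, baseline)


@pytest.fixture(scope="session")
def baseline_fluxes(model, baseline, baseline_activities):
    return cf.evaluate_fluxes(model, baseline, baseline_activities, 0.0)


@pytest.fixture(scope="session")
def flat_dataset(model, baseline):
    """Noise-free steady-state dataset (both replicates equal the truth)."""
    scen = cf.make_scenario(model, None)
    return cf.generate_dataset(model, scen, x0=baseline,
                               noise_low_high=(1.0, 1.0), seed=11)


@pytest.fixture(scope="session")
def toy_chain():
    """3-pool linear chain with one inflow and one outflow: boundary
    inflow -> A -> B -> C -> out, hand-solvable steady state."""
    cfg = dict(
        pools=[
            dict(id=1, role="DHC", chain="C18"),
            dict(id=2, role="DHC", chain="C18:1"),
            dict(id=3, role="DHC", chain="C24/C24:1"),
        ],
        fluxes=[
            dict(id=1, enzyme_class="remodelase", consumes=[], produces=[1],
                 boundary_inputs=["FA"]),
            dict(id=2, enzyme_class="elongase", consumes=[1], produces=[2]),
            dict(id=3, enzyme_class="elongase", consumes=[2], produces=[3]),
            dict(id=4, enzyme_class="elongase", consumes=[3], produces=[]),
        ],
        drivers={"FA": 2.0},
        groups={"inflow": [1]},
        unconstrained_fluxes=[2, 3, 4],
    )
    return cf.build_ceramide_network(cfg)


def rhs_bruteforce(model, state, activities, t=0.0):
    """Independent S.v assembly straight from the FluxSpec lists."""
    rates = cf.evaluate_fluxes(model, state, activities, t)
    dx = np.zeros(model.n_pools)
    for j, fx in enumerate(model.fluxes):
        for pid in fx.produces:
            dx[pid - 1] += rates[j]
        for pid in fx.consumes:
            dx[pid - 1] -= rates[j]
    return dx
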