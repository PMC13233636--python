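from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import glusyn as g

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def receptor_params():
    return g.ReceptorParams()


@pytest.fixture(scope="session")
def transport_params():
    return g.TransportParams()


@pytest.fixture(scope="session")
def plasticity_params():
    return g.PlasticityParams()


@pytest.fixture(scope="session")
def neuron_params():
    return g.NeuronParams()


@pytest.fixture(scope="session")
def train50():
    """The default stimulation protocol: 5 pulses at 50 Hz from t = 10 ms."""
    return g.StimulusTrain.periodic()


@pytest.fixture(scope="session")
def ampa_sims(train50):
    """AMPA-isolated voltage-clamp responses at -80 mV (cell 2), both conditions."""
    p = g.table_params(2).replace(receptor=replace(g.ReceptorParams(), gbar_nmda=0.0))
    clamp = g.ClampSpec(mode="vc", V_h=-80.0)
    return {
        "control": g.simulate(p, train50, clamp, g.Condition.control(), t_end=300.0),
        "tboa": g.simulate(p, train50, clamp, g.Condition.blockade(2.0), t_end=300.0),
    }


@pytest.fixture(scope="session")
def nmda_sims(train50):
    """NMDA-isolated voltage-clamp responses at -20 mV (cell 3), both conditions.

    The blockade run is simulated over a longer window because extrasynaptic
    clearance is then limited by bulk diffusion (~1.2 s), so the decay would
    otherwise not complete inside the trace.
    """
    p = g.table_params(3).replace(receptor=replace(g.ReceptorParams(), gbar_ampa=0.0))
    clamp = g.ClampSpec(mode="vc", V_h=-20.0)
    return {
        "control": g.simulate(p, train50, clamp, g.Condition.control(), t_end=1500.0),
        "tboa": g.simulate(p, train50, clamp, g.Condition.blockade(2.0), t_end=3500.0),
    }


@pytest.fixture(scope="session")
def voltage_pair_sims(train50):
    """NMDA responses at -20 vs +40 mV holding, two- and one-compartment models."""
    p = g.table_params(3).replace(receptor=replace(g.ReceptorParams(), gbar_ampa=0.0))
    out = {}
    for one_comp in (False, True):
        for vh in (-20.0, 40.0):
            clamp = g.ClampSpec(mode="vc", V_h=vh, one_compartment=one_comp)
            key = ("1comp" if one_comp else "2comp", vh)
            out[key] = g.simulate(p, train50, clamp, g.Condition.control(), t_end=400.0)
    return out
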