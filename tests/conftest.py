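import pytest

import viaspace as vs


@pytest.fixture(scope="session")
def toy():
    """Canonical 9-reaction universe with its environment and biomass."""
    universe, env, biomass = vs.toy9()
    return universe, env, biomass


@pytest.fixture(scope="session")
def toy_evaluator(toy):
    universe, env, biomass = toy
    return vs.ViabilityEvaluator(universe, env, biomass)


@pytest.fixture(scope="session")
def toy_viable(toy):
    """Exhaustive viable sets V(n) of the canonical universe, keyed by n."""
    universe, env, biomass = toy
    return {n: vs.enumerate_viable(universe, env, biomass, n) for n in range(3, 10)}


@pytest.fixture(scope="session")
def two_carbon():
    universe, env1, env2, biomass = vs.toy9_two_carbon()
    return universe, env1, env2, biomass
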