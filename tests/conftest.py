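import numpy as np
import pytest

import limnoweb as lw


@pytest.fixture(scope="session")
def kaptai():
    return lw.kaptai_fixture()


@pytest.fixture(scope="session")
def balanced(kaptai):
    return lw.solve(kaptai)


@pytest.fixture(scope="session")
def network(balanced):
    return lw.build_flow_network(balanced)


@pytest.fixture(scope="session")
def spine(balanced):
    return lw.lindeman_spine(balanced)


def make_chain_model(
    producer_b=1.0,
    producer_pb=10.0,
    consumer_b=0.1,
    consumer_qb=10.0,
    consumer_pb=2.0,
    landings=0.0,
    diet_on_producer=1.0,
):
    """Minimal producer -> consumer chain with an inert detritus pool."""
    groups = [
        lw.FunctionalGroup("algae", lw.GroupType.PRODUCER, biomass=producer_b, pb=producer_pb),
        lw.FunctionalGroup(
            "grazer",
            lw.GroupType.CONSUMER,
            biomass=consumer_b,
            pb=consumer_pb,
            qb=consumer_qb,
            landings=landings,
        ),
        lw.FunctionalGroup("detritus", lw.GroupType.DETRITUS, biomass=1.0, unassimilated=0.0),
    ]
    names = [g.name for g in groups]
    entries = np.zeros((3, 3))
    entries[0, 1] = diet_on_producer
    entries[2, 1] = 1.0 - diet_on_producer
    diet = lw.DietMatrix(group_names=names, entries=entries)
    return lw.FoodWebModel(groups=groups, diet=diet)
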