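import numpy as np
import pytest

from raftsim.engine import DomainSpec, SimConfig
from raftsim.membrane import BoxSpec, MotionParams
from raftsim.reactions import ReactionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def box():
    return BoxSpec(30.0)


@pytest.fixture
def no_domain():
    return DomainSpec(count=0, occupied_percent=0.0)


@pytest.fixture
def small_config(no_domain):
    """A quick-running configuration for functional tests."""
    return SimConfig(
        domains=no_domain,
        n_steps=2_000,
        window=1_000,
        thin=10,
        replicates=2,
        seed=7,
    )


@pytest.fixture
def strict_config(no_domain):
    """Hard-disc configuration: tangent dissociation + reaction veto,
    under which the all-pairs no-overlap invariant holds at every state."""
    return SimConfig(
        domains=no_domain,
        reactions=ReactionParams(dissociation_placement="tangent",
                                 reaction_overlap_veto=True),
        n_steps=1_000,
        window=500,
        thin=10,
        replicates=1,
        seed=11,
    )
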