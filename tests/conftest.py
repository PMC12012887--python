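import numpy as np
import pytest

from relic.intracellular import layered_gene_expression_circuit
from relic.resources import CompetitiveReaction, ReactionKind, ResourcePool


@pytest.fixture
def pool100():
    return ResourcePool("pool", R_tot=100.0)


@pytest.fixture
def unimolecular_reaction():
    return CompetitiveReaction(
        ReactionKind.UNIMOLECULAR, beta_star=2.0, substrates=("S",),
        product="P", pool_id="pool", w_u=1.0,
    )


@pytest.fixture
def layered_model():
    """Layered controller at its reference parameterization (Sigma = r* = 1)."""
    return layered_gene_expression_circuit()


@pytest.fixture
def layered_start(layered_model):
    return layered_model.state_vector({"x1": 0.0, "z1": 0.1, "z2": 50.0})
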