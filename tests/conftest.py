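import numpy as np
import pytest
from hypothesis import settings

from retrorank.featurization import FingerprintConfig
from retrorank.models import FFEBM, FFEBMConfig, GraphEBM, GraphEBMConfig
from retrorank.synthetic import (
    SyntheticSpec,
    generate_fragment_library,
    generate_proposals,
    generate_reactions,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_FP = FingerprintConfig(length=512)


@pytest.fixture(scope="session")
def library():
    return generate_fragment_library(60, seed=7)


@pytest.fixture(scope="session")
def reactions(library):
    return generate_reactions(library, 40, seed=7)


@pytest.fixture(scope="session")
def proposal_table(reactions):
    spec = SyntheticSpec(n_products=40, k_candidates=6, library_size=60, seed=7)
    return generate_proposals(reactions, spec)


@pytest.fixture()
def tiny_ff():
    cfg = FFEBMConfig(fingerprint=SMALL_FP, embed_dim=8, hidden_dim=8,
                      out_hidden_dim=8)
    return FFEBM(cfg, seed=3)


@pytest.fixture()
def tiny_graph():
    cfg = GraphEBMConfig(hidden_dim=8, embed_dim=8, out_hidden_dim=8, t_steps=2)
    return GraphEBM(cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
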