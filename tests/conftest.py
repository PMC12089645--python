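import numpy as np
import pytest

from ampfp.synth import CommunityModel, SynthConfig, make_benchmark_world


@pytest.fixture(scope="session")
def small_world():
    """Held-out-query world: 20 bacterial + 8 archaeal tips, 25% held out."""
    cfg = SynthConfig(seed=1, n_tips_bacteria=20, n_tips_archaea=8)
    return make_benchmark_world(cfg)


@pytest.fixture(scope="session")
def tips_world():
    """Exact-reference-query world used for perfect-recovery checks."""
    cfg = SynthConfig(
        seed=2,
        n_tips_bacteria=20,
        n_tips_archaea=8,
        community_model=CommunityModel(n_samples=5),
    )
    return make_benchmark_world(cfg, query_mode="tips")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
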