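import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("arraymeta").setLevel(logging.WARNING)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_tree(tmp_path):
    """A 3-study, 12-gene synthetic tree with two injected effects."""
    from arraymeta.synth import SynthConfig, generate_tree

    cfg = SynthConfig(
        n_studies=3,
        n_genes=12,
        samples_per_group=6,
        seed=7,
        effect_genes={"GENE0001": 1.5, "GENE0002": -1.5},
        linear_scale_studies=frozenset({2}),
    )
    truth = generate_tree(cfg, tmp_path / "tree")
    return tmp_path / "tree", cfg, truth
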