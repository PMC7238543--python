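import pytest

from fcmkit import load_fixture, scale_weights
from fcmkit.synth import SynthConfig, generate_map


def random_map(seed, n_nodes=6, n_edges=10, inhibitory_prob=0.25, scaled=True):
    """Small seeded random map for closure property tests."""
    cfg = SynthConfig(
        n_nodes=n_nodes,
        n_edges=n_edges,
        inhibitory_prob=inhibitory_prob,
        n_categories=min(3, n_nodes),
        seed=seed,
        name=f"rand{seed}",
    )
    fcm, mapping = generate_map(cfg)
    return (scale_weights(fcm) if scaled else fcm), mapping


@pytest.fixture
def toy_maps():
    return load_fixture("toy_maps")


@pytest.fixture
def chain3(toy_maps):
    return toy_maps["chain3"]["map"]
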