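import numpy as np
import pytest

from selsort.synthgen import (
    Recording,
    SimConfig,
    generate_ground_truth,
    make_templates,
    render_channel,
)


@pytest.fixture()
def rng():
    """Fresh, identically-seeded generator per test: results never depend
    on test execution order."""
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """3-neuron, 5 s render at moderate noise with forced overlaps."""
    cfg = SimConfig(
        duration=120000,
        firing_rates=(0.0008, 0.0008, 0.0008),
        noise_level=0.1,
        seed=7,
        overlap_rate=0.05,
    )
    templates = make_templates(3, cfg.tau, seed=cfg.seed)
    truth = generate_ground_truth(cfg, templates)
    rec = render_channel(truth, cfg)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def clean_single_sim():
    """Noise-free single neuron: every spike an exact template copy."""
    cfg = SimConfig(
        duration=120000, firing_rates=(0.0006,), noise_level=0.0, seed=3
    )
    templates = make_templates(1, cfg.tau, seed=cfg.seed)
    truth = generate_ground_truth(cfg, templates)
    rec = render_channel(truth, cfg)
    return rec, truth, cfg


def three_blob_features(rng, n_per=80, d=4, sep=8.0):
    """Well-separated Gaussian blobs for clustering fixtures."""
    centers = sep * np.eye(d)[:3]
    X = np.concatenate(
        [c + rng.normal(size=(n_per, d)) for c in centers]
    )
    labels = np.repeat(np.arange(3), n_per)
    return X, labels
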