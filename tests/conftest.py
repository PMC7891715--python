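"""Shared fixtures: a small synthetic scene and a trained separation.

Session-scoped so the (moderately expensive) PC-NMF training runs once and
is reused by the separation, phenology, and diversity tests.
"""

import numpy as np
import pytest

from soundscapeir import pcnmf, synthetic


@pytest.fixture(scope="session")
def scene():
    """2-day three-source scene (broadband abiotic, dusk chorus, nocturnal
    transients) with ground truth."""
    sources = synthetic.default_sources()[:3]
    config = synthetic.SceneConfig(duration_days=2.0, sources=sources, seed=42)
    grid, truth = synthetic.generate_ltsa_scene(config)
    return config, grid, truth


@pytest.fixture(scope="session")
def separation(scene):
    """Trained PC-NMF model with predicted activations and reconstruction."""
    _, grid, truth = scene
    folded = pcnmf.fold(grid, 30)
    model = pcnmf.train(
        folded, n_features=12, n_sources=3, iterations=120, seed=7
    )
    H = pcnmf.predict_activations(model, folded, iterations=120, seed=8)
    sep = pcnmf.reconstruct(model, folded, H)
    return {
        "grid": grid,
        "truth": truth,
        "folded": folded,
        "model": model,
        "H": H,
        "sep": sep,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
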