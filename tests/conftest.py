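"""Shared fixtures.

Heavy artefacts (trained models, multi-round pipeline runs) are
session-scoped so several test modules can assert against one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from woundseg.assl import ASSLConfig, ASSLRunner
from woundseg.model import TrainingConfig, UNetSegmenter
from woundseg.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_pretraining_set,
)


@pytest.fixture(scope="session")
def blob_mask() -> np.ndarray:
    """A deterministic single-component wound-like mask, 64x64."""
    cfg = SyntheticConfig(n_images=1, seed=11, hard_fraction=0.0)
    samples, _ = generate_dataset(cfg)
    return samples[0].truth_mask.copy()


@pytest.fixture(scope="session")
def easy_dataset():
    """40 full-contrast synthetic samples (no hard cases)."""
    cfg = SyntheticConfig(n_images=40, seed=1, hard_fraction=0.0)
    samples, manifest = generate_dataset(cfg)
    return samples, manifest


@pytest.fixture(scope="session")
def trained_easy_model(easy_dataset):
    """Tiny U-Net fitted on 30 easy samples; 10 held out."""
    samples, _ = easy_dataset
    X = np.stack([s.pixels for s in samples])
    y = np.stack([s.truth_mask for s in samples])
    est = UNetSegmenter(epochs=30, learning_rate=1e-3, seed=0)
    est.fit(X[:30], y[:30])
    return est, X, y


@pytest.fixture(scope="session")
def mini_pretrained():
    """Source-domain model for mini pipeline runs (reduced sizes)."""
    base = generate_pretraining_set(60, seed=7001)
    X = np.stack([s.pixels for s in base])
    y = np.stack([s.truth_mask for s in base])
    est = UNetSegmenter(epochs=25, learning_rate=1e-3, seed=0)
    est.fit(X, y)
    state = est.state_
    state.provenance = "pretrained-synthetic-base"
    return state


@pytest.fixture(scope="session")
def mini_dataset():
    """50-image target dataset for mini pipeline runs."""
    cfg = SyntheticConfig(n_images=50, seed=42)
    samples, _ = generate_dataset(cfg)
    return samples


def _mini_config(seed: int = 3) -> ASSLConfig:
    return ASSLConfig(
        target_correct_fraction=0.999,  # never met: exercises 3 full rounds
        max_rounds=3,
        plateau_patience=3,
        val_fraction=0.10,
        seed=seed,
        training=TrainingConfig(epochs=10, learning_rate=1e-3, seed=seed),
    )


@pytest.fixture(scope="session")
def mini_run(mini_pretrained, mini_dataset):
    """A seeded 3-round pipeline run on 50 images (structural checks)."""
    runner = ASSLRunner(mini_pretrained, _mini_config())
    history = runner.run(mini_dataset)
    return runner, history
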