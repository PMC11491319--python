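"""Shared fixtures: deterministic phantom datasets for classifier tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from lungcbo import phantom, preprocess


def make_texture_dataset(n: int, seed: int, image_size: int = 64, equalized: bool = True):
    """Balanced benign/malignant phantoms whose class signal is texture-only.

    Both classes share identical shape statistics (no spiculation); malignant
    nodules carry stronger intra-nodule texture. Returns (X, y) with y = 1
    for malignant.
    """
    labels = np.array([phantom.MALIGNANT] * (n // 2) + [phantom.BENIGN] * (n - n // 2))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    base = phantom.PhantomSpec(image_size=image_size, nodule_radius_px=8.0, texture_contrast=8.0)
    X, y = [], []
    for i, lab in enumerate(labels):
        spec = replace(
            phantom.spec_for_class(base, lab, phantom._child_seed(seed, i)),
            spiculation_amplitude=0.0,
        )
        img, _, _ = phantom.generate_phantom(spec)
        if equalized:
            img = preprocess.equalize(img)
        X.append(img)
        y.append(1 if lab == phantom.MALIGNANT else 0)
    return np.stack(X), np.array(y)


@pytest.fixture(scope="session")
def small_texture_dataset():
    """120 texture-separated 64x64 phantoms, shared across classifier tests."""
    return make_texture_dataset(120, seed=7)
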