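"""Shared fixtures: small synthetic datasets and rendered images."""

from __future__ import annotations

import numpy as np
import pytest

import ecgsift as es


@pytest.fixture(scope="session")
def short_records():
    """30 records (10 per class) of 30 s at 128 Hz — quick but rhythmic."""
    return es.generate_dataset(
        {"ARR": 10, "CHF": 10, "NSR": 10}, seed=11, n_samples=3840
    )


@pytest.fixture(scope="session")
def full_record():
    """One full-length (65,535-sample) normal-sinus-rhythm record."""
    return es.generate_record("NSR", seed=1, n_samples=65_535, sampling_rate=128)


@pytest.fixture(scope="session")
def ecg_image(full_record):
    """Default 200x200 rendering of the first segment of a full record."""
    seg = es.preprocess_record(full_record)[0]
    return es.render_segment(seg)


@pytest.fixture(scope="session")
def blob_image():
    """A smooth grayscale test image with isolated bright blobs."""
    rng = np.random.default_rng(42)
    h = w = 64
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for _ in range(6):
        cy, cx = rng.uniform(12, h - 12, 2)
        sigma = rng.uniform(1.5, 3.0)
        amp = rng.uniform(0.5, 1.0)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return img / img.max()
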