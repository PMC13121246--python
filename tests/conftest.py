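"""Shared fixtures: tiny images, manifests, and the desk-scale trained run."""

from __future__ import annotations

import numpy as np
import pytest

from drgrade.io import DatasetManifest, FundusImage, ManifestRecord
from drgrade.pipeline import run_desk_scale


def make_records_manifest(counts, prefix="img", origin="primary", split="unassigned"):
    """Records-only manifest with the given per-class counts."""
    records = []
    for grade, count in enumerate(counts):
        for i in range(count):
            records.append(ManifestRecord(id=f"{prefix}_g{grade}_{i:04d}", path="",
                                          grade=grade, split=split, origin=origin))
    return DatasetManifest(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    pixels = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    return FundusImage(pixels=pixels, grade=2, id="rand16")


@pytest.fixture
def messidor_shaped_manifest():
    """A manifest with the class counts of a typical imbalanced grading set."""
    return make_records_manifest([1017, 270, 347, 75, 35])


@pytest.fixture(scope="session")
def desk_run():
    """The canonical desk-scale study: 100 synthetic images per class at
    side 256, two-member ensemble trained for 10 epochs. Expensive; shared
    across every test that needs a trained ensemble."""
    return run_desk_scale(n_per_class=100, image_side=256, input_side=96,
                          epochs=10, seed=1)
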