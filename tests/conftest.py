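"""Shared fixtures: small phantom scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from gratio import generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """12 clean near-circular fibers, noise-free, design g-ratio 0.6."""
    return generate_scene(256, 256, 12, (6, 14), {}, seed=11)


@pytest.fixture(scope="session")
def defect_scene():
    """23 fibers: 12 clean + 5 oblique + 3 incomplete + 3 undersized."""
    return generate_scene(
        512,
        512,
        23,
        (8, 20),
        {"oblique": 5 / 23, "incomplete": 3 / 23, "undersized": 3 / 23},
        seed=3,
    )


def match_design(scene, centroid):
    """The designed fiber whose center is nearest a measured centroid."""
    return min(
        scene.fibers,
        key=lambda fd: (fd.center[0] - centroid[0]) ** 2 + (fd.center[1] - centroid[1]) ** 2,
    )


@pytest.fixture(scope="session")
def random_mask_pairs():
    """100 random 64x64 label-mask pairs for metric oracle checks."""
    rng = np.random.default_rng(42)
    return [
        (rng.integers(0, 3, size=(64, 64)), rng.integers(0, 3, size=(64, 64)))
        for _ in range(100)
    ]
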