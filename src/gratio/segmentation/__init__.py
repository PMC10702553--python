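"""Per-class probability maps for {background, myelin, axon}.

Two interchangeable backends produce :class:`ProbabilityMaps`: the
trainable encoder--decoder network (:func:`train` / :func:`predict`) and a
deterministic oracle (:func:`oracle_predict`) that converts a ground-truth
mask into near-one-hot probabilities with optional seeded corruption.  All
downstream stages consume the same contract, so the oracle serves as a
perfect-segmentation test double for the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gratio.mask import LabelMask, VALID_CODES

CLASS_ORDER = ("background", "myelin", "axon")


@dataclass
class ProbabilityMaps:
    """3 x H x W class probabilities in the fixed order (background, myelin, axon)."""

    maps: np.ndarray
    source: str = "oracle"
    class_order: tuple[str, str, str] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[0] != 3:
            raise ValueError(f"maps must have shape (3, H, W), got {self.maps.shape}")
        if self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.maps.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("per-pixel probabilities must sum to 1 within 1e-5")
        if self.source not in ("network", "oracle"):
            raise ValueError("source must be 'network' or 'oracle'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def argmax_labels(self) -> np.ndarray:
        return self.maps.argmax(axis=0)


def oracle_predict(
    mask: LabelMask | np.ndarray,
    flip_rate: float = 0.0,
    seed: int = 0,
    confidence: float = 0.99,
) -> ProbabilityMaps:
    """Near-one-hot probabilities from a ground-truth mask.

    The true class of each pixel receives ``confidence`` probability mass,
    the other two classes split the remainder.  With ``flip_rate > 0``,
    exactly ``floor(flip_rate * H * W)`` distinct pixels (chosen by the
    seeded generator) have their dominant class replaced by one of the
    other two, so at ``flip_rate = 0`` the argmax reproduces the mask
    exactly.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must lie in (0.5, 1) so the argmax is the dominant class")
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if labels.ndim != 2 or (labels.size and not np.isin(labels, VALID_CODES).all()):
        raise ValueError("mask must be a 2-D array of codes {0,1,2}")
    h, w = labels.shape
    assigned = labels.copy()
    n_flip = int(np.floor(flip_rate * h * w))
    if n_flip:
        rng = np.random.default_rng(seed)
        flat = rng.choice(h * w, size=n_flip, replace=False)
        offsets = rng.integers(1, 3, size=n_flip)
        flat_labels = assigned.ravel()
        flat_labels[flat] = (flat_labels[flat] + offsets) % 3
        assigned = flat_labels.reshape(h, w)
    off = (1.0 - confidence) / 2.0
    maps = np.full((3, h, w), off)
    for c in VALID_CODES:
        maps[c][assigned == c] = confidence
    return ProbabilityMaps(maps=maps, source="oracle")


from gratio.segmentation.model import (  # noqa: E402  (re-exports)
    TrainConfig,
    UNet,
    load_model,
    predict,
    save_model,
    train,
)

__all__ = [
    "CLASS_ORDER",
    "ProbabilityMaps",
    "oracle_predict",
    "TrainConfig",
    "UNet",
    "train",
    "predict",
    "save_model",
    "load_model",
]
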