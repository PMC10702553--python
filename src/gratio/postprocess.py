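"""Probability-map thresholding and cavity filling.

The segmentation probability maps are converted to a clean 3-class label
mask in two steps: per-pixel thresholding at 0.8 (a pixel is assigned to a
class whose probability reaches the threshold, with priority
axon > myelin > background on ties; pixels where no class reaches the
threshold fall back to the per-pixel argmax), then filling of enclosed
background cavities larger than 5 pixels inside axon or myelin regions.

The cavity rule is applied literally: only holes with area strictly above
``min_cavity_px`` are filled by default.  Because the more common
convention fills *small* holes instead, the direction is switchable via
``fill_direction`` (``"larger"``, the default, or ``"smaller"``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from gratio.mask import AXON, BACKGROUND, MYELIN, LabelMask
from gratio.segmentation import ProbabilityMaps

#: Probability threshold for class assignment.
DEFAULT_THRESHOLD = 0.8
#: Cavity area threshold in pixels.
DEFAULT_MIN_CAVITY_PX = 5

# 4-connectivity for background holes, 8-connectivity for foreground
# regions: the standard digital-topology duality.
_STRUCT_HOLES = ndimage.generate_binary_structure(2, 1)
_STRUCT_FG = ndimage.generate_binary_structure(2, 2)


def threshold_probabilities(
    prob: ProbabilityMaps,
    threshold: float = DEFAULT_THRESHOLD,
    pixel_size_um: float | None = None,
) -> LabelMask:
    """Assign each pixel to a class by thresholding the probability maps.

    Priority on simultaneous threshold passes is axon > myelin > background;
    pixels where no class passes are assigned by argmax (same priority on
    exact probability ties).
    """
    if not isinstance(prob, ProbabilityMaps):
        raise ValueError("prob must be a ProbabilityMaps instance")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    maps = prob.maps
    # argmax with axon-first priority on ties: scan classes in reversed order
    rev = maps[::-1]  # (axon, myelin, background)
    labels = 2 - rev.argmax(axis=0)
    passed = maps >= threshold
    for code in (BACKGROUND, MYELIN, AXON):  # ascending priority; later wins
        labels = np.where(passed[code], code, labels)
    from gratio.mask import DEFAULT_PIXEL_SIZE_UM

    return LabelMask(labels.astype(np.int64), pixel_size_um or DEFAULT_PIXEL_SIZE_UM)


def fill_cavities(
    mask: LabelMask,
    min_cavity_px: int = DEFAULT_MIN_CAVITY_PX,
    fill_direction: str = "larger",
) -> LabelMask:
    """Relabel enclosed background cavities to their surrounding class.

    A cavity is a 4-connected background component that does not touch the
    image border and whose 8-neighbourhood contains only foreground; it is
    relabelled to the majority class among its neighbouring foreground
    pixels.  ``fill_direction="larger"`` fills cavities with area strictly
    greater than ``min_cavity_px``; ``"smaller"`` fills those with area at
    most ``min_cavity_px``.  The operation is idempotent and never converts
    foreground to background.
    """
    if fill_direction not in ("larger", "smaller"):
        raise ValueError("fill_direction must be 'larger' or 'smaller'")
    labels = mask.labels.copy()
    background = labels == BACKGROUND
    comp, n_comp = ndimage.label(background, structure=_STRUCT_HOLES)
    if n_comp == 0:
        return LabelMask(labels, mask.pixel_size_um)

    border = np.zeros_like(background)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(comp[border & background])
    areas = ndimage.sum_labels(background, comp, index=np.arange(1, n_comp + 1))

    for comp_id in range(1, n_comp + 1):
        if comp_id in border_ids:
            continue
        area = areas[comp_id - 1]
        fill = area > min_cavity_px if fill_direction == "larger" else area <= min_cavity_px
        if not fill:
            continue
        hole = comp == comp_id
        ring = ndimage.binary_dilation(hole, _STRUCT_FG) & ~hole
        ring_labels = labels[ring]
        n_myelin = int((ring_labels == MYELIN).sum())
        n_axon = int((ring_labels == AXON).sum())
        if n_myelin + n_axon == 0:  # pragma: no cover - non-border hole has neighbours
            continue
        labels[hole] = AXON if n_axon >= n_myelin else MYELIN
    return LabelMask(labels, mask.pixel_size_um)
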