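"""Three-class label masks and their on-disk representation.

Class codes follow the convention used throughout the package:
``0`` background (black), ``1`` myelin (white), ``2`` axon (gray).
Masks are stored as single-channel 8-bit PNG/TIFF files holding the raw
codes, so a round trip through disk is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

BACKGROUND = 0
MYELIN = 1
AXON = 2

VALID_CODES = (BACKGROUND, MYELIN, AXON)

#: Default sampling of the scanned sections, micrometres per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.05


@dataclass
class LabelMask:
    """A 2-D semantic mask with codes {0=background, 1=myelin, 2=axon}.

    Parameters
    ----------
    labels
        2-D integer array of class codes.
    pixel_size_um
        Physical size of one pixel in micrometres (must be positive).
    """

    labels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and not np.isin(self.labels, VALID_CODES).all():
            bad = sorted(set(np.unique(self.labels)) - set(VALID_CODES))
            raise ValueError(f"labels contain codes outside {{0,1,2}}: {bad}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        """Pixel count per class code."""
        return {c: int(np.count_nonzero(self.labels == c)) for c in VALID_CODES}

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.pixel_size_um)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as a single-channel 8-bit image holding the raw codes."""
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_mask(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> LabelMask:
    """Read a mask written by :func:`write_mask` (lossless round trip)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # grayscale PNG readers may add a channel axis
        arr = arr[..., 0]
    return LabelMask(arr.astype(np.int64), pixel_size_um)
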