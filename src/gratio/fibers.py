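"""Fiber instance extraction and morphometric selection.

A fiber instance is one 8-connected axon component together with the
myelin pixels that belong to it.  The mask itself does not say which
myelin ring wraps which axon, so myelin pixels are assigned to the axon
component they are geodesically closest to *through the myelin class* — a
seeded watershed on the axon-plus-myelin support with the axon components
as seeds.  Myelin components with no axon reachable are left unassigned
and reported separately.

Selection applies the morphometric quality filters on the axon region:
a fiber is excluded if the axon is highly elongated (eccentricity > 0.95),
not compact (solidity < 0.9) or too small (area < 50 pixels).  The
inequalities are strict, so the boundary values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops
from skimage.segmentation import watershed

from gratio.mask import AXON, MYELIN, LabelMask

_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class SelectionCriteria:
    """Exclusion thresholds applied to the axon region (strict inequalities)."""

    max_eccentricity: float = 0.95
    min_solidity: float = 0.9
    min_area_px: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.max_eccentricity < 1):
            raise ValueError("max_eccentricity must lie in (0, 1)")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must lie in (0, 1]")
        if self.min_area_px <= 0:
            raise ValueError("min_area_px must be positive")


@dataclass
class FiberInstance:
    """One axon component with its assigned myelin and shape descriptors."""

    fiber_id: int
    axon_pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    myelin_pixels: tuple[np.ndarray, np.ndarray]
    axon_area_px: int
    axon_eccentricity: float
    axon_solidity: float
    centroid: tuple[float, float]
    touches_border: bool = False
    selected: bool = True
    exclusion_reasons: frozenset = frozenset()

    @property
    def myelin_area_px(self) -> int:
        return len(self.myelin_pixels[0])


def extract_fibers(
    mask: LabelMask, return_unassigned: bool = False
) -> list[FiberInstance] | tuple[list[FiberInstance], np.ndarray]:
    """Extract one :class:`FiberInstance` per connected axon component.

    Axon components are labelled with 8-connectivity in row-major discovery
    order (fiber ids are therefore deterministic).  Every myelin pixel from
    which some axon is reachable through the axon-or-myelin support is
    assigned to exactly one fiber by a seeded watershed (geodesic-nearest
    axon); the remaining myelin pixels form the *unassigned* set, returned
    as a boolean array when ``return_unassigned`` is true.
    """
    labels = mask.labels
    axon = labels == AXON
    myelin = labels == MYELIN
    axon_cc, n_axon = ndimage.label(axon, structure=_STRUCT_8)
    if n_axon == 0:
        return ([], myelin.copy()) if return_unassigned else []

    support = axon | myelin
    # constant-image watershed floods outward from the axon seeds, so each
    # myelin pixel joins the geodesically nearest axon component
    flooded = watershed(np.zeros_like(axon_cc), markers=axon_cc, mask=support)
    unassigned = myelin & (flooded == 0)

    fibers: list[FiberInstance] = []
    props = {p.label: p for p in regionprops(axon_cc)}
    for comp_id in range(1, n_axon + 1):
        p = props[comp_id]
        axon_px = np.nonzero(axon_cc == comp_id)
        myelin_px = np.nonzero((flooded == comp_id) & myelin)
        r0, c0, r1, c1 = p.bbox
        touches = r0 == 0 or c0 == 0 or r1 == labels.shape[0] or c1 == labels.shape[1]
        fibers.append(
            FiberInstance(
                fiber_id=comp_id - 1,
                axon_pixels=axon_px,
                myelin_pixels=myelin_px,
                axon_area_px=int(p.area),
                axon_eccentricity=float(p.eccentricity),
                axon_solidity=float(p.solidity),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                touches_border=touches,
            )
        )
    return (fibers, unassigned) if return_unassigned else fibers


def select_fibers(
    fibers: list[FiberInstance],
    criteria: SelectionCriteria = SelectionCriteria(),
    exclude_border: bool = False,
) -> list[FiberInstance]:
    """Flag each fiber as selected or excluded; order is preserved.

    A fiber is excluded iff eccentricity > ``max_eccentricity``, solidity
    < ``min_solidity``, or axon area < ``min_area_px`` (strict
    comparisons); ``exclude_border`` additionally rejects fibers whose
    axon bounding box touches the image border.  The filter is pure and
    idempotent: descriptors are not recomputed.
    """
    out = []
    for f in fibers:
        reasons = set()
        if f.axon_eccentricity > criteria.max_eccentricity:
            reasons.add("eccentricity")
        if f.axon_solidity < criteria.min_solidity:
            reasons.add("solidity")
        if f.axon_area_px < criteria.min_area_px:
            reasons.add("area")
        if exclude_border and f.touches_border:
            reasons.add("border")
        out.append(
            FiberInstance(
                fiber_id=f.fiber_id,
                axon_pixels=f.axon_pixels,
                myelin_pixels=f.myelin_pixels,
                axon_area_px=f.axon_area_px,
                axon_eccentricity=f.axon_eccentricity,
                axon_solidity=f.axon_solidity,
                centroid=f.centroid,
                touches_border=f.touches_border,
                selected=not reasons,
                exclusion_reasons=frozenset(reasons),
            )
        )
    return out


def fibers_table(fibers: list[FiberInstance]) -> pd.DataFrame:
    """Per-fiber descriptor table (one row per instance)."""
    return pd.DataFrame(
        [
            {
                "fiber_id": f.fiber_id,
                "centroid_row": f.centroid[0],
                "centroid_col": f.centroid[1],
                "axon_area_px": f.axon_area_px,
                "myelin_area_px": f.myelin_area_px,
                "eccentricity": f.axon_eccentricity,
                "solidity": f.axon_solidity,
                "touches_border": f.touches_border,
                "selected": f.selected,
                "exclusion_reasons": "|".join(sorted(f.exclusion_reasons)),
            }
            for f in fibers
        ],
        columns=[
            "fiber_id",
            "centroid_row",
            "centroid_col",
            "axon_area_px",
            "myelin_area_px",
            "eccentricity",
            "solidity",
            "touches_border",
            "selected",
            "exclusion_reasons",
        ],
    )


def instance_maps(fibers: list[FiberInstance], shape: tuple[int, int]) -> np.ndarray:
    """2 x H x W uint16 instance-id maps (axon ids, myelin ids; 0 = none)."""
    out = np.zeros((2,) + shape, dtype=np.uint16)
    for f in fibers:
        out[0][f.axon_pixels] = f.fiber_id + 1
        out[1][f.myelin_pixels] = f.fiber_id + 1
    return out
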