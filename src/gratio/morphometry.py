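"""Per-fiber morphometry: diameters, volume fractions and the g-ratio.

For one fiber the reference region is the union of its axon and myelin
pixels, so the axon and myelin volume (area) fractions satisfy
``AVF + MVF = 1`` and the g-ratio

    g = sqrt(1 / (1 + MVF / AVF)) = sqrt(|axon| / |region|)

reduces to the classical inner/outer radius ratio ``r / R`` for an ideal
annulus.  Diameters use the area-equivalent circle (``2 * sqrt(area / pi)``),
which is robust to boundary pixelation; myelin thickness is half the
difference between the fiber and axon equivalent diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gratio.fibers import FiberInstance


@dataclass
class FiberMorphometrics:
    """Morphometric summary of a single fiber (physical units)."""

    fiber_id: int
    axon_diameter_um: float
    myelin_thickness_um: float
    avf: float
    mvf: float
    g_ratio: float
    unmyelinated: bool = False

    def __post_init__(self) -> None:
        if not self.axon_diameter_um > 0:
            raise ValueError("axon_diameter_um must be positive")
        if self.myelin_thickness_um < 0:
            raise ValueError("myelin_thickness_um must be >= 0")
        if not (0 < self.avf <= 1 and 0 <= self.mvf < 1):
            raise ValueError("volume fractions out of range")
        if abs(self.avf + self.mvf - 1.0) > 1e-12:
            raise ValueError("AVF + MVF must equal 1 for the per-fiber region")
        expected_g = math.sqrt(1.0 / (1.0 + self.mvf / self.avf))
        if abs(self.g_ratio - expected_g) > 1e-12:
            raise ValueError("g_ratio inconsistent with sqrt(1/(1+MVF/AVF))")


def compute_morphometrics(fiber: FiberInstance, pixel_size_um: float) -> FiberMorphometrics:
    """Compute AVF, MVF, g-ratio, axon diameter and myelin thickness.

    An empty myelin set yields ``mvf = 0``, ``g_ratio = 1`` and zero
    thickness with the ``unmyelinated`` flag raised (exclusion is the
    selection module's concern, not this one's).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    n_axon = fiber.axon_area_px
    if n_axon <= 0:
        raise ValueError("fiber has an empty axon")
    n_myelin = fiber.myelin_area_px
    n_region = n_axon + n_myelin
    avf = n_axon / n_region
    mvf = n_myelin / n_region
    axon_d = 2.0 * math.sqrt(n_axon / math.pi) * pixel_size_um
    fiber_d = 2.0 * math.sqrt(n_region / math.pi) * pixel_size_um
    g = math.sqrt(avf)  # = sqrt(1/(1+MVF/AVF)) since AVF+MVF=1
    return FiberMorphometrics(
        fiber_id=fiber.fiber_id,
        axon_diameter_um=axon_d,
        myelin_thickness_um=(fiber_d - axon_d) / 2.0,
        avf=avf,
        mvf=mvf,
        g_ratio=g,
        unmyelinated=(n_myelin == 0),
    )


_METRICS = ("axon_diameter_um", "myelin_thickness_um", "avf", "mvf", "g_ratio")


def morphometrics_table(rows: list[FiberMorphometrics], selected_flags=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "fiber_id": r.fiber_id,
                "axon_diameter_um": r.axon_diameter_um,
                "myelin_thickness_um": r.myelin_thickness_um,
                "avf": r.avf,
                "mvf": r.mvf,
                "g_ratio": r.g_ratio,
                "unmyelinated": r.unmyelinated,
            }
            for r in rows
        ]
    )
    if selected_flags is not None:
        df.insert(1, "selected", list(selected_flags))
    return df


def aggregate_morphometrics(rows: list[FiberMorphometrics]) -> dict:
    """Mean, sample SD (n-1 denominator) and n for each metric.

    With a single row the SD is reported as 0.0 and the ``single_row``
    flag is set, since the sample SD is undefined at n = 1.
    """
    if not rows:
        raise ValueError("aggregate_morphometrics needs at least one fiber")
    n = len(rows)
    out: dict = {"n": n, "single_row": n == 1}
    for metric in _METRICS:
        values = np.array([getattr(r, metric) for r in rows], dtype=float)
        out[metric] = {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if n > 1 else 0.0,
        }
    return out
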