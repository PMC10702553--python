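"""Synthetic stained-nerve cross-section phantoms with exact ground truth.

The generator lays down non-overlapping myelinated fibers (elliptical axon
surrounded by a concentric myelin ring) on a background and renders a
stylized stained appearance.  Each scene carries a per-fiber design table,
so every downstream stage — segmentation, selection, morphometry — can be
validated against known truth.

Besides clean near-circular fibers, the generator plants the nuisance
structures that the morphometric selection filters must reject:

``oblique``
    strongly elongated axon ellipse (eccentricity > 0.95), emulating a fiber
    sectioned non-perpendicular to its axis;
``incomplete``
    a wedge sector (120 degrees) removed from axon and myelin, emulating a
    partially captured fiber; the notched axon has solidity < 0.9;
``undersized``
    axon area below 50 pixels, too small for reliable morphometry.

Rasterization uses a pixel-center-inside test: pixel ``(r, c)`` belongs to
an ellipse iff its integer center lies inside the continuous ellipse.  Area
oracles in tests count pixels with exactly this rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from gratio.mask import AXON, BACKGROUND, DEFAULT_PIXEL_SIZE_UM, MYELIN, LabelMask, write_mask

DEFECT_TYPES = ("none", "oblique", "incomplete", "undersized")

#: Wedge angle removed from "incomplete" fibers, radians.  A 120-degree
#: notch drops the solidity of the remaining axon to ~0.71, safely below
#: the 0.9 selection threshold, while keeping eccentricity moderate.
INCOMPLETE_WEDGE_RAD = 2.0 * np.pi / 3.0

TRUTH_COLUMNS = [
    "fiber_id",
    "center_row",
    "center_col",
    "axon_r_a",
    "axon_r_b",
    "outer_r_a",
    "outer_r_b",
    "rotation",
    "defect",
    "true_g_ratio",
    "true_axon_diameter_um",
    "true_myelin_thickness_um",
]


@dataclass
class FiberDesign:
    """Ground-truth geometry of one designed fiber.

    ``axon_radii`` and ``myelin_outer_radii`` are semi-axes in pixels,
    ``(a, b)`` with ``a >= b``; the myelin ring is the area between the
    outer ellipse and the axon ellipse.  True morphometrics use the
    area-equivalent radii ``sqrt(a*b)`` so they coincide with the circle
    values for circular fibers.
    """

    center: tuple[float, float]
    axon_radii: tuple[float, float]
    myelin_outer_radii: tuple[float, float]
    rotation: float
    defect: str
    true_g_ratio: float
    true_axon_diameter_um: float
    true_myelin_thickness_um: float
    wedge_start: float = 0.0  # only meaningful for defect="incomplete"

    def __post_init__(self) -> None:
        a, b = self.axon_radii
        A, B = self.myelin_outer_radii
        if not (A > a and B > b and a >= b > 0):
            raise ValueError(
                f"myelin must strictly enclose the axon: axon ({a}, {b}), outer ({A}, {B})"
            )
        if self.defect not in DEFECT_TYPES:
            raise ValueError(f"unknown defect {self.defect!r}; one of {DEFECT_TYPES}")
        if not 0.0 < self.true_g_ratio < 1.0:
            raise ValueError("true_g_ratio must lie in (0, 1)")


@dataclass
class PhantomScene:
    """Rendered phantom: intensity image, label mask and fiber designs."""

    image: np.ndarray
    mask: LabelMask
    fibers: list[FiberDesign]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    stain_style: str = "PPD_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def _ellipse_support(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    rotation: float,
    wedge: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean support of a rotated ellipse by the pixel-center-inside rule.

    ``wedge=(start, extent)`` removes the angular sector
    ``[start, start+extent)`` (angle measured in the ellipse's local frame).
    """
    cr, cc = center
    a, b = radii
    reach = int(np.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(np.floor(cr)) - reach), min(shape[0], int(np.ceil(cr)) + reach + 1)
    c0, c1 = max(0, int(np.floor(cc)) - reach), min(shape[1], int(np.ceil(cc)) + reach + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros(shape, dtype=bool)
    rr, cc_grid = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr = rr - cr
    dc = cc_grid - cc
    ct, st = np.cos(rotation), np.sin(rotation)
    x = dc * ct + dr * st  # along semi-major axis a
    y = -dc * st + dr * ct  # along semi-minor axis b
    inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    if wedge is not None:
        start, extent = wedge
        ang = np.mod(np.arctan2(y, x) - start, 2.0 * np.pi)
        inside &= ang >= extent
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = inside
    return out


def rasterize_fiber(
    fiber: FiberDesign, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one fiber; returns boolean (axon, myelin) supports."""
    wedge = None
    if fiber.defect == "incomplete":
        wedge = (fiber.wedge_start, INCOMPLETE_WEDGE_RAD)
    outer = _ellipse_support(shape, fiber.center, fiber.myelin_outer_radii, fiber.rotation, wedge)
    axon = _ellipse_support(shape, fiber.center, fiber.axon_radii, fiber.rotation, wedge)
    return axon, outer & ~axon


def _sample_design(
    rng: np.random.Generator,
    defect: str,
    radius_range: tuple[float, float],
    g_ratio: float,
    pixel_size_um: float,
    aspect_range: tuple[float, float],
) -> dict:
    """Draw the geometry of one fiber of the requested defect type."""
    rmin, rmax = radius_range
    if defect == "none":
        r = rng.uniform(rmin, rmax)
        aspect = rng.uniform(*aspect_range)  # a/b <= 1.2 keeps eccentricity <= 0.55
        a, b = r * np.sqrt(aspect), r / np.sqrt(aspect)
    elif defect == "oblique":
        # b/a = 1/4 gives continuous eccentricity sqrt(1 - 1/16) ~ 0.968
        a = rng.uniform(max(16.0, rmin), max(22.0, rmin + 6.0))
        b = a / 4.0
    elif defect == "incomplete":
        r = rng.uniform(max(9.0, rmin), max(12.0, rmax))
        a = b = r
    elif defect == "undersized":
        # pi * 3.7^2 ~ 43 px: below the 50 px area threshold even after
        # rasterization jitter, yet round enough to pass the other filters
        r = rng.uniform(3.2, 3.7)
        a = b = r
    else:  # pragma: no cover - guarded upstream
        raise ValueError(defect)
    A, B = a / g_ratio, b / g_ratio
    r_eq, r_out_eq = float(np.sqrt(a * b)), float(np.sqrt(A * B))
    return {
        "axon_radii": (float(a), float(b)),
        "myelin_outer_radii": (float(A), float(B)),
        "rotation": float(rng.uniform(0.0, np.pi)),
        "wedge_start": float(rng.uniform(0.0, 2.0 * np.pi)),
        "true_g_ratio": r_eq / r_out_eq,
        "true_axon_diameter_um": 2.0 * r_eq * pixel_size_um,
        "true_myelin_thickness_um": (r_out_eq - r_eq) * pixel_size_um,
    }


def _defect_schedule(n_fibers: int, defect_fractions: dict[str, float] | None) -> list[str]:
    """Exact per-fiber defect assignment: count = round(fraction * n)."""
    fractions = dict(defect_fractions or {})
    for name, frac in fractions.items():
        if name not in DEFECT_TYPES or name == "none":
            raise ValueError(f"invalid defect key {name!r}")
        if frac < 0:
            raise ValueError("defect fractions must be >= 0")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("defect fractions must sum to <= 1")
    schedule: list[str] = []
    for name in ("oblique", "incomplete", "undersized"):
        schedule += [name] * int(round(fractions.get(name, 0.0) * n_fibers))
    if len(schedule) > n_fibers:
        raise ValueError("rounded defect counts exceed n_fibers")
    schedule += ["none"] * (n_fibers - len(schedule))
    return schedule


_STYLES = {
    "PPD_like": {"background": 0.92, "myelin": 0.12, "axon": 0.55, "textured_bg": False},
    "TB_like": {"background": 0.88, "myelin": 0.45, "axon": 0.70, "textured_bg": True},
}


def _render(
    mask: np.ndarray,
    stain_style: str,
    noise_sd: float,
    blur_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    style = _STYLES[stain_style]
    img = np.full(mask.shape, style["background"], dtype=np.float64)
    img[mask == MYELIN] = style["myelin"]
    img[mask == AXON] = style["axon"]
    if style["textured_bg"]:
        # low-frequency mottle on the background, as in toluidine-blue sections
        field = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=8.0)
        field /= max(np.abs(field).max(), 1e-12)
        img[mask == BACKGROUND] += 0.05 * field[mask == BACKGROUND]
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_scene(
    width: int = 512,
    height: int = 512,
    n_fibers: int = 30,
    radius_range: tuple[float, float] = (8.0, 20.0),
    defect_fractions: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    stain_style: str = "PPD_like",
    seed: int = 0,
    g_ratio: float = 0.6,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    aspect_range: tuple[float, float] = (1.0, 1.2),
    min_gap_px: int = 1,
    max_attempts_per_fiber: int = 500,
) -> PhantomScene:
    """Generate a phantom scene with ``n_fibers`` disjoint fibers.

    Fibers are placed by rejection sampling: a candidate position is kept
    only if its full support (outer ellipse) stays inside the image and at
    least ``min_gap_px`` pixels away from every fiber already placed.
    ``defect_fractions`` maps defect names (``oblique``, ``incomplete``,
    ``undersized``) to fractions of ``n_fibers``; counts are
    ``round(fraction * n)`` and the remainder are clean fibers.  The design
    g-ratio (axon over outer equivalent radius) is ``g_ratio`` for every
    fiber.  Identical seeds give bit-identical scenes.

    Raises
    ------
    RuntimeError
        If a fiber cannot be placed within ``max_attempts_per_fiber``
        attempts — the requested density exceeds what the image can hold.
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if stain_style not in _STYLES:
        raise ValueError(f"unknown stain_style {stain_style!r}; one of {sorted(_STYLES)}")
    if not 0.0 < g_ratio < 1.0:
        raise ValueError("g_ratio must lie in (0, 1)")
    rmin, rmax = radius_range
    if not 0 < rmin <= rmax:
        raise ValueError("radius_range must satisfy 0 < min <= max")
    if rmax / g_ratio * 2 > min(width, height):
        raise ValueError("radius_range too large for the image")

    rng = np.random.default_rng(seed)
    shape = (height, width)
    schedule = _defect_schedule(n_fibers, defect_fractions)

    mask = np.zeros(shape, dtype=np.int64)
    occupied = np.zeros(shape, dtype=bool)
    fibers: list[FiberDesign] = []
    struct = ndimage.generate_binary_structure(2, 2)

    for fiber_idx, defect in enumerate(schedule):
        geom = _sample_design(rng, defect, radius_range, g_ratio, pixel_size_um, aspect_range)
        reach = max(geom["myelin_outer_radii"]) + 1.0
        placed = False
        for _ in range(max_attempts_per_fiber):
            center = (
                float(rng.uniform(reach, height - 1 - reach)),
                float(rng.uniform(reach, width - 1 - reach)),
            )
            fiber = FiberDesign(center=center, defect=defect, **geom)
            axon_px, myelin_px = rasterize_fiber(fiber, shape)
            support = axon_px | myelin_px
            halo = support
            if min_gap_px > 0:
                halo = ndimage.binary_dilation(support, struct, iterations=min_gap_px)
            if not (halo & occupied).any():
                mask[myelin_px] = MYELIN
                mask[axon_px] = AXON
                occupied |= support
                fibers.append(fiber)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place fiber {fiber_idx + 1}/{n_fibers} after "
                f"{max_attempts_per_fiber} attempts: requested density exceeds "
                f"the {width}x{height} image capacity for radii {radius_range}"
            )

    image = _render(mask, stain_style, noise_sd, blur_sigma, rng)
    return PhantomScene(
        image=image,
        mask=LabelMask(mask, pixel_size_um),
        fibers=fibers,
        pixel_size_um=pixel_size_um,
        stain_style=stain_style,
        seed=seed,
    )


def scene_truth_table(scene: PhantomScene) -> pd.DataFrame:
    """Per-fiber design table with true morphometrics in physical units."""
    rows = []
    for i, f in enumerate(scene.fibers):
        rows.append(
            {
                "fiber_id": i,
                "center_row": f.center[0],
                "center_col": f.center[1],
                "axon_r_a": f.axon_radii[0],
                "axon_r_b": f.axon_radii[1],
                "outer_r_a": f.myelin_outer_radii[0],
                "outer_r_b": f.myelin_outer_radii[1],
                "rotation": f.rotation,
                "defect": f.defect,
                "true_g_ratio": f.true_g_ratio,
                "true_axon_diameter_um": f.true_axon_diameter_um,
                "true_myelin_thickness_um": f.true_myelin_thickness_um,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_scene(scene: PhantomScene, out_dir: str | Path) -> dict[str, Path]:
    """Write image (8-bit TIFF), mask (PNG, codes {0,1,2}) and truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.tif",
        "mask": out / "mask.png",
        "truth": out / "truth.csv",
    }
    tifffile.imwrite(paths["image"], np.round(scene.image * 255).astype(np.uint8))
    write_mask(scene.mask, paths["mask"])
    scene_truth_table(scene).to_csv(paths["truth"], index=False)
    return paths
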