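"""Slide coordinate frame, circular counting zones, and patch-grid generation.

All geometry lives in a single canonical unit: microns in the level-0 slide
frame (origin top-left, x rightward, y downward, the usual image convention).
Pixel inputs are converted on ingest via the slide's microns-per-pixel (mpp),
so that zone areas — which pathologists specify in mm² — are magnification
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

__all__ = [
    "SlideFrame",
    "PointUm",
    "CircleZone",
    "PatchGrid",
    "area_to_radius",
    "distance",
    "build_patch_grid",
    "circles_intersect",
]


class PointUm(NamedTuple):
    """A point in microns, level-0 frame (x rightward, y downward)."""

    x: float
    y: float


@dataclass(frozen=True)
class SlideFrame:
    """Physical coordinate frame of one whole-slide image level 0.

    Parameters
    ----------
    mpp : float
        Microns per pixel at level 0. Scanners in routine breast pathology
        produce e.g. 0.24 µm/px; the value is configurable, never assumed.
    width_px, height_px : int
        Slide extent in level-0 pixels.
    slide_id : str
        Opaque identifier carried through all outputs.
    """

    mpp: float
    width_px: int
    height_px: int
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not (self.mpp > 0):
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide extent must be at least 1x1 pixels")

    @property
    def width_um(self) -> float:
        return self.width_px * self.mpp

    @property
    def height_um(self) -> float:
        return self.height_px * self.mpp

    def px_to_um(self, x_px: float, y_px: float) -> PointUm:
        return PointUm(x_px * self.mpp, y_px * self.mpp)

    def um_to_px(self, p: PointUm) -> tuple[float, float]:
        return (p.x / self.mpp, p.y / self.mpp)


def area_to_radius(area_mm2: float) -> float:
    """Radius in microns of a circle of the given area in mm².

    r = sqrt(A/π); e.g. a 1 mm² counting zone has radius ≈ 564.19 µm and a
    2 mm² zone ≈ 797.88 µm.
    """
    if not (area_mm2 > 0):
        raise ValueError(f"area must be positive, got {area_mm2}")
    return math.sqrt(area_mm2 / math.pi) * 1000.0


@dataclass(frozen=True)
class CircleZone:
    """A circular counting zone (center in µm, radius in µm)."""

    center: PointUm
    radius_um: float

    def __post_init__(self) -> None:
        if not (self.radius_um > 0):
            raise ValueError(f"radius must be positive, got {self.radius_um}")

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radius_um**2 / 1e6

    @classmethod
    def from_area(cls, center: PointUm, area_mm2: float) -> "CircleZone":
        return cls(center=center, radius_um=area_to_radius(area_mm2))


def distance(a: PointUm, b: PointUm) -> float:
    """Euclidean distance in microns."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


def circles_intersect(a: CircleZone, b: CircleZone) -> bool:
    """Whether two zones overlap; tangent circles count as intersecting.

    The inclusive convention (≤, not <) mirrors the inclusive distance test
    used for radius counting throughout the pipeline.
    """
    return distance(a.center, b.center) <= a.radius_um + b.radius_um


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping patch tiling restricted to tumor regions.

    ``centers`` holds the micron coordinates of patch centers whose center
    point lies inside (or on) a tumor polygon. ``stride_um`` is the patch
    edge in microns, i.e. patch_px · level_mpp.
    """

    patch_px: int
    level_mpp: float
    centers: tuple[PointUm, ...] = field(default_factory=tuple)

    @property
    def stride_um(self) -> float:
        return self.patch_px * self.level_mpp


def build_patch_grid(
    regions: Sequence[Polygon],
    patch_px: int = 256,
    level_mpp: float = 0.48,
    frame: SlideFrame | None = None,
) -> PatchGrid:
    """Tile the tumor regions into non-overlapping square patches.

    The grid is axis aligned, phase anchored at the top-left corner of the
    joint bounding box of all regions, with stride ``patch_px * level_mpp``
    microns. A tile contributes its center iff that center lies inside or on
    any region polygon (membership by center point, matching patch
    classification semantics where a patch is labeled by dominant content).

    Parameters
    ----------
    regions : sequence of shapely Polygon
        Invasive-carcinoma outlines, coordinates in microns.
    patch_px : int
        Patch edge in pixels (default 256).
    level_mpp : float
        Microns per pixel at the tiling magnification. Default 0.48 µm/px,
        i.e. 256 px ≙ 122.88 µm at 20× for slides scanned at 0.24 µm/px.
    frame : SlideFrame, optional
        If given, the grid is clipped to the slide extent.

    Notes
    -----
    The result is invariant under reordering of the region list, and empty
    regions (or polygons with zero area) simply contribute no centers.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    if not (level_mpp > 0):
        raise ValueError("level_mpp must be positive")

    polys = [p for p in regions if p is not None and not p.is_empty and p.area > 0]
    if not polys:
        return PatchGrid(patch_px=patch_px, level_mpp=level_mpp, centers=())

    stride = patch_px * level_mpp
    minx = min(p.bounds[0] for p in polys)
    miny = min(p.bounds[1] for p in polys)
    maxx = max(p.bounds[2] for p in polys)
    maxy = max(p.bounds[3] for p in polys)
    if frame is not None:
        minx, miny = max(minx, 0.0), max(miny, 0.0)
        maxx = min(maxx, frame.width_um)
        maxy = min(maxy, frame.height_um)

    nx = max(1, math.ceil((maxx - minx) / stride - 1e-9))
    ny = max(1, math.ceil((maxy - miny) / stride - 1e-9))
    xs = minx + (np.arange(nx) + 0.5) * stride
    ys = miny + (np.arange(ny) + 0.5) * stride

    prepared = [prep(p) for p in polys]
    centers: list[PointUm] = []
    for y in ys:
        for x in xs:
            pt = Point(x, y)
            # covers (not contains) so boundary centers count as inside
            if any(pp.covers(pt) for pp in prepared):
                centers.append(PointUm(float(x), float(y)))
    return PatchGrid(patch_px=patch_px, level_mpp=level_mpp, centers=tuple(centers))
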