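"""Calibrated binary masks, section stacks, and the atlas grid.

Masks are binary occupancy rasters of the thyroid in one view, calibrated in
mm per pixel.  Registered masks live on an :class:`AtlasGrid`, a continuous
mm window of the canonical frame discretized at a fixed resolution with the
origin of pixel indexing at the grid's upper-left corner (row 0 holds the
largest second-axis coordinate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import Polygon
from shapely import contains_xy

__all__ = [
    "AtlasGrid",
    "Mask",
    "SectionStack",
    "front_grid",
    "section_grid",
    "read_mask",
    "write_mask",
    "mask_area",
    "rasterize_polygon",
]


@dataclass(frozen=True)
class AtlasGrid:
    """Discretized window of the canonical frame for one view.

    ``x_range`` spans the mediolateral axis; ``second_range`` spans Y (front)
    or Z (section).  Cell centers sit at half-pixel offsets; the second-axis
    coordinate decreases with the row index.
    """

    view: str
    x_range: tuple = (-4.0, 4.0)
    second_range: tuple = (-7.0, 1.0)
    resolution: float = 0.02

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.x_range[1] <= self.x_range[0] or self.second_range[1] <= self.second_range[0]:
            raise ValueError("ranges must be increasing")

    @property
    def n_cols(self) -> int:
        return int(round((self.x_range[1] - self.x_range[0]) / self.resolution))

    @property
    def n_rows(self) -> int:
        return int(round((self.second_range[1] - self.second_range[0]) / self.resolution))

    @property
    def shape(self) -> tuple:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        return self.x_range[0] + (np.arange(self.n_cols) + 0.5) * self.resolution

    def second_centers(self) -> np.ndarray:
        """Second-axis cell centers, descending with row index (row 0 on top)."""
        return self.second_range[1] - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_centers(self):
        """Meshgrid of (x, second) cell-center coordinates, shape = grid shape."""
        xx, ss = np.meshgrid(self.x_centers(), self.second_centers())
        return xx, ss


def front_grid(resolution: float = 0.02) -> AtlasGrid:
    """Default ventral-view atlas window: X in [-4, 4], Y in [-7, 1] mm."""
    return AtlasGrid("front", (-4.0, 4.0), (-7.0, 1.0), resolution)


def section_grid(resolution: float = 0.02) -> AtlasGrid:
    """Default section-view atlas window: X in [-3, 3], Z in [-1, 3] mm."""
    return AtlasGrid("section", (-3.0, 3.0), (-1.0, 3.0), resolution)


@dataclass
class Mask:
    """Binary thyroid-occupancy raster with mm calibration.

    ``grid`` is set when the mask lives on an atlas grid (after registration
    or rasterization); raw image masks have ``grid=None`` and exist in their
    own pixel space.
    """

    pixels: np.ndarray
    pixel_size: float
    view: str
    specimen_id: str = ""
    grid: AtlasGrid | None = field(default=None)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixels = px.astype(bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (missing calibration?)")
        if self.view not in ("front", "section"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.grid is not None and self.grid.shape != self.pixels.shape:
            raise ValueError("pixel array does not match the atlas grid shape")

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2


def mask_area(m: Mask) -> float:
    """Mask area in mm²: count of foreground pixels times pixel_size²."""
    return m.area_mm2


def read_mask(path, *, pixel_size: float | None = None, view: str = "front",
              specimen_id: str = "", sidecar: dict | None = None) -> Mask:
    """Read a PNG or TIFF mask; any nonzero value in any channel is foreground.

    Calibration comes either from ``pixel_size`` or a ``sidecar`` dict with
    keys ``pixel_size_mm``/``view``/``specimen_id``.
    """
    if sidecar is not None:
        pixel_size = sidecar.get("pixel_size_mm", pixel_size)
        view = sidecar.get("view", view)
        specimen_id = sidecar.get("specimen_id", specimen_id)
    if pixel_size is None:
        raise ValueError(f"no pixel-size calibration supplied for {path}")
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(Image.open(p))
    if arr.ndim == 3:
        arr = arr.any(axis=-1)
    binary = arr != 0
    if not binary.any():
        warnings.warn(f"mask {path} is empty", stacklevel=2)
    return Mask(binary, pixel_size, view, specimen_id)


def write_mask(m: Mask, path) -> None:
    """Write a binary mask as 8-bit PNG or TIFF (foreground = 255)."""
    arr = (m.pixels.astype(np.uint8)) * 255
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(p, arr)
    else:
        Image.fromarray(arr).save(p)


def rasterize_polygon(poly_mm, grid: AtlasGrid, specimen_id: str = "") -> Mask:
    """Rasterize a simple polygon (mm vertices) onto an atlas grid.

    A pixel is foreground iff its center lies strictly inside the polygon
    (unbiased pixel-center rule).  Self-intersecting polygons are rejected;
    zero-area polygons yield an empty mask.
    """
    verts = np.asarray(poly_mm, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        if verts.size == 0 or verts.shape[0] < 3:
            return Mask(np.zeros(grid.shape, bool), grid.resolution, grid.view,
                        specimen_id, grid)
        raise ValueError("polygon must be an (N, 2) vertex array")
    rel = verts - verts[0]
    collinear = np.all(np.abs(rel[:, 0] * rel[1, 1] - rel[:, 1] * rel[1, 0]) < 1e-15)
    if collinear:  # degenerate zero-area polygon: valid empty mask
        return Mask(np.zeros(grid.shape, bool), grid.resolution, grid.view,
                    specimen_id, grid)
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    xx, ss = grid.cell_centers()
    inside = contains_xy(poly, xx.ravel(), ss.ravel()).reshape(grid.shape)
    return Mask(inside, grid.resolution, grid.view, specimen_id, grid)


@dataclass
class SectionStack:
    """Ordered transverse sections of one specimen.

    ``planes`` is a list of ``(offset, Mask)`` where ``offset`` is the cutting
    depth in mm measured caudally from the upper border of the thyroid
    cartilage (canonical Y of the plane is ``-offset``).  Offsets must be
    strictly increasing with uniform spacing equal to ``interval``.
    """

    specimen_id: str
    planes: list
    interval: float = 0.5

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        offsets = np.array([o for o, _ in self.planes], dtype=float)
        if len(offsets) > 1:
            steps = np.diff(offsets)
            if np.any(steps <= 0):
                raise ValueError("plane offsets must be strictly increasing")
            if np.any(np.abs(steps - self.interval) > 1e-9):
                raise ValueError("plane spacing must equal the stated interval")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.planes], dtype=float)

    @property
    def masks(self) -> list:
        return [m for _, m in self.planes]

    def plane_y(self) -> np.ndarray:
        """Canonical Y coordinate of each cutting plane (negative = caudal)."""
        return -self.offsets

    def __len__(self) -> int:
        return len(self.planes)
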