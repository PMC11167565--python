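"""Site-dependent incidence atlases, threshold regions, and central points.

After registration, each atlas cell records the fraction of specimens whose
thyroid covers it (k/N).  Thresholding at ≥ 50 % or 100 % yields the incident
regions; their per-axis minimum/maximum extents give lobe measurements, and
the midpoint of the extents on each axis defines the lobe's central point.
Stacking the per-phase regions in enlargement order produces the
phase-dependent topography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import AtlasGrid, Mask
from .volumetry import PHASE_ORDER, PHASES

__all__ = [
    "IncidenceMap",
    "Region",
    "CentralPoint",
    "Topography",
    "build_incidence_map",
    "threshold_region",
    "split_lobes",
    "region_extents",
    "central_point",
    "merge_topography",
]

_TOL = 1e-12


@dataclass
class IncidenceMap:
    """Per-cell fraction of specimens covering each atlas location."""

    view: str
    grid: AtlasGrid
    values: np.ndarray
    n_specimens: int
    phase: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("values do not match the grid shape")
        if self.n_specimens < 1:
            raise ValueError("need at least one specimen")
        if v.min() < -_TOL or v.max() > 1 + _TOL:
            raise ValueError("incidence values must lie in [0, 1]")
        self.values = v


@dataclass
class Region:
    """Thresholded incidence region (binary) on the atlas grid."""

    pixels: np.ndarray
    grid: AtlasGrid
    tau: float
    phase: str = ""
    lobe: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.shape != self.grid.shape:
            raise ValueError("pixels do not match the grid shape")

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.grid.resolution**2


@dataclass(frozen=True)
class CentralPoint:
    """Per-lobe 3-D central point: each coordinate is the midpoint of the
    region's minimum and maximum extent on that axis, in mm."""

    lobe: str
    x: float
    y: float
    z: float


@dataclass
class Topography:
    """Ordered (phase, Region) overlay for one view and one threshold."""

    view: str
    tau: float
    entries: list = field(default_factory=list)

    def phases(self) -> list:
        return [p for p, _ in self.entries]


def build_incidence_map(masks, phase: str = "") -> IncidenceMap:
    """Per-pixel specimen coverage fraction from registered masks.

    All masks must live on the same atlas grid; the value at a cell is the
    number of masks covering it divided by the number of masks.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    if grid is None:
        raise ValueError("masks must be registered onto an atlas grid")
    for m in masks:
        if m.grid != grid or m.view != grid.view:
            raise ValueError("all masks must share the same atlas grid and view")
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.pixels
    return IncidenceMap(grid.view, grid, counts / float(len(masks)), len(masks), phase)


def threshold_region(imap: IncidenceMap, tau: float) -> Region:
    """Cells with incidence ≥ τ (inclusive: 3/6 belongs to the ≥ 50 % region).

    τ = 1 selects exact unanimity (within floating tolerance), the 100 %
    incidence region.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    return Region(imap.values >= tau - _TOL, imap.grid, tau, imap.phase)


def split_lobes(r: Region) -> tuple:
    """Split a region at the canonical midline into (left, right) lobes.

    Left lobe = x > 0 (the animal's left is the +X side), right = x < 0.
    Columns centered exactly on the midline are assigned to the side holding
    the majority of their connected component.
    """
    x = r.grid.x_centers()
    left = r.pixels & (x > 0)[None, :]
    right = r.pixels & (x < 0)[None, :]
    mid_cols = x == 0
    if mid_cols.any() and (r.pixels & mid_cols[None, :]).any():
        labels, n = ndimage.label(r.pixels)
        for lab in range(1, n + 1):
            comp = labels == lab
            comp_mid = comp & mid_cols[None, :]
            if not comp_mid.any():
                continue
            n_left = int((comp & (x > 0)[None, :]).sum())
            n_right = int((comp & (x < 0)[None, :]).sum())
            if n_left >= n_right:
                left |= comp_mid
            else:
                right |= comp_mid
    mk = lambda px, lobe: Region(px, r.grid, r.tau, r.phase, lobe)
    return mk(left, "left"), mk(right, "right")


def _box_extents(pixels: np.ndarray, grid: AtlasGrid):
    """Pixel-box extents (x_min, x_max, s_min, s_max) of a non-empty region.

    Extents are measured on pixel boxes (cell center ± half resolution), so a
    region rasterized from edges on grid lines recovers those edges exactly.
    """
    rows = np.flatnonzero(pixels.any(axis=1))
    cols = np.flatnonzero(pixels.any(axis=0))
    h = grid.resolution / 2.0
    xc = grid.x_centers()
    sc = grid.second_centers()
    return (
        float(xc[cols.min()] - h),
        float(xc[cols.max()] + h),
        float(sc[rows.max()] - h),
        float(sc[rows.min()] + h),
    )


def region_extents(r: Region) -> dict:
    """Lobe measurements (mm) from the region's extents.

    Front view: ``length_mm`` is the craniocaudal (Y) extent and ``width_mm``
    the widest mediolateral run within any row — the lobe's width at a level,
    which for the obliquely running lobes is narrower than the full X extent.
    Section view: ``thickness_mm`` is the anteroposterior (Z) extent and
    ``width_mm`` the full X extent.  ``medial_mm``/``lateral_mm`` are the
    minimum/maximum |x| of the region.  All extents use pixel boxes.
    """
    if r.is_empty:
        raise ValueError("cannot measure an empty region")
    grid = r.grid
    res = grid.resolution
    x0, x1, s0, s1 = _box_extents(r.pixels, grid)
    xc = grid.x_centers()
    occupied = np.abs(xc[r.pixels.any(axis=0)])
    out = {
        "x_min_mm": x0,
        "x_max_mm": x1,
        "medial_mm": max(float(occupied.min()) - res / 2.0, 0.0),
        "lateral_mm": float(occupied.max()) + res / 2.0,
    }
    if grid.view == "front":
        widths = []
        for row in r.pixels:
            cols = np.flatnonzero(row)
            if cols.size:
                widths.append((cols.max() - cols.min() + 1) * res)
        out["length_mm"] = s1 - s0
        out["width_mm"] = float(max(widths))
        out["y_min_mm"], out["y_max_mm"] = s0, s1
    else:
        out["thickness_mm"] = s1 - s0
        out["width_mm"] = x1 - x0
        out["z_min_mm"], out["z_max_mm"] = s0, s1
    return out


def central_point(
    lobe_front: Region | None,
    lobe_section: Region,
    plane_offset: float | None = None,
    lobe: str = "",
) -> CentralPoint:
    """3-D central point of one lobe from its 100 %-incidence regions.

    X and Z are the midpoints of the section region's extents.  Y is the
    canonical Y of the section plane when a single plane was cut (the
    default reading), otherwise the midpoint of the front region's Y extent.
    """
    if lobe_section is None or lobe_section.is_empty:
        raise ValueError("section region is empty; no central point")
    x0, x1, z0, z1 = _box_extents(lobe_section.pixels, lobe_section.grid)
    if plane_offset is not None:
        y = float(plane_offset)
    else:
        if lobe_front is None or lobe_front.is_empty:
            raise ValueError("front region needed when no section plane is given")
        _, _, y0, y1 = _box_extents(lobe_front.pixels, lobe_front.grid)
        y = (y0 + y1) / 2.0
    return CentralPoint(
        lobe or lobe_section.lobe, (x0 + x1) / 2.0, y, (z0 + z1) / 2.0
    )


def merge_topography(maps, tau: float) -> tuple:
    """Merge per-phase incidence maps into a phase-ordered topography.

    Returns ``(Topography, extent_table)`` where the table holds per-phase,
    per-lobe extents for trend checks.  Requires one map per phase (duplicate
    phases are an error); phases are ordered native → T>15.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no incidence maps to merge")
    view = maps[0].view
    seen = {}
    for m in maps:
        if m.view != view or m.grid != maps[0].grid:
            raise ValueError("maps must share one view and grid")
        if m.phase in seen:
            raise ValueError(f"duplicate phase {m.phase!r}")
        if m.phase not in PHASE_ORDER:
            raise ValueError(f"unknown phase {m.phase!r}")
        seen[m.phase] = m
    ordered = [seen[p] for p in PHASES if p in seen]
    topo = Topography(view, tau)
    rows = []
    for m in ordered:
        region = threshold_region(m, tau)
        topo.entries.append((m.phase, region))
        if region.is_empty:
            continue
        for lobe_region in split_lobes(region):
            if lobe_region.is_empty:
                continue
            row = {"phase": m.phase, "lobe": lobe_region.lobe, "tau": tau}
            row.update(region_extents(lobe_region))
            rows.append(row)
    if all(reg.is_empty for _, reg in topo.entries):
        warnings.warn("all threshold regions are empty", stacklevel=2)
    return topo, pd.DataFrame(rows)
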