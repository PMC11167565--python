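"""Deterministic reference fixture cohorts built from the printed lobe extents.

Separate from the stochastic generator, these cohorts consist of N identical,
noise-free specimens whose lobes are simple polygons with exactly the
published native and largest-phase measurements.  They serve as the ground
truth for exact pipeline checks: with zero jitter the 100 %-incidence region
must equal every input mask, so the atlas must return the printed extents and
central points to rasterization precision.

Native front lobes are slanted parallelograms 2 mm long with a constant
0.6 mm mediolateral width at every level, running from 0.5 mm off the
midline at the proximal (cranial) end to 1.5 mm at the distal end and
centered at the cricoid-ring level (Y = -2).  The largest-phase ("T>15")
lobe is a 4 mm long band, up to 1.6 mm wide, 0.1 mm off the midline
proximally, with its center shifted 0.5 mm caudally.  Section-view lobes are
axis-aligned rectangles reproducing the printed thickness/width and the
tabulated central points (left 1.0, -2.0, 1.1; right -0.9, -2.0, 1.0).
"""

from __future__ import annotations

import numpy as np

from .frames import image_mm_to_px, load_skeleton_template
from .raster import Mask, SectionStack, front_grid, rasterize_polygon, section_grid
from .pipeline import SpecimenRecord

__all__ = [
    "REFERENCE_PHASES",
    "reference_polygons",
    "reference_specimens",
    "reference_truth",
]

REFERENCE_PHASES = ("native", "T>15")

# image placement of the canonical origin (must match the atlas grid layout)
_FRONT_BASE = np.array([4.0, -1.0])
_SECTION_BASE = np.array([3.0, -3.0])

#: single cutting plane of the reference stacks: 2 mm below the upper border
REFERENCE_PLANE_DEPTH = 2.0


def _mirror(poly):
    return [(-x, y) for x, y in poly]


def reference_polygons(phase: str) -> dict:
    """Lobe polygons (canonical mm) of one reference phase, per view and side."""
    if phase == "native":
        front_left = [(0.5, -1.0), (1.1, -1.0), (1.5, -3.0), (0.9, -3.0)]
        section_left = [(0.7, 0.7), (1.3, 0.7), (1.3, 1.5), (0.7, 1.5)]
        section_right = [(-1.2, 0.6), (-0.6, 0.6), (-0.6, 1.4), (-1.2, 1.4)]
    elif phase == "T>15":
        front_left = [
            (0.1, -0.5), (0.9, -0.5), (1.7, -2.0), (1.7, -3.0),
            (1.5, -4.5), (0.7, -4.5), (0.1, -3.5), (0.1, -1.5),
        ]
        section_left = [(0.4, 0.3), (1.6, 0.3), (1.6, 1.9), (0.4, 1.9)]
        section_right = [(-1.6, 0.2), (-0.4, 0.2), (-0.4, 1.8), (-1.6, 1.8)]
    else:
        raise ValueError(f"no reference fixture for phase {phase!r}")
    return {
        "front": {"left": front_left, "right": _mirror(front_left)},
        "section": {"left": section_left, "right": section_right},
    }


def reference_truth(phase: str) -> dict:
    """Expected atlas measurements of the reference fixture (mm)."""
    if phase == "native":
        return {
            "length_mm": 2.0,
            "width_mm": 0.6,
            "central_point": {"left": (1.0, -2.0, 1.1), "right": (-0.9, -2.0, 1.0)},
        }
    if phase == "T>15":
        return {
            "length_mm": 4.0,
            "width_mm": 1.6,
            "central_point": {"left": (1.0, -2.0, 1.1), "right": (-1.0, -2.0, 1.0)},
        }
    raise ValueError(f"no reference fixture for phase {phase!r}")


def _image_mask(polys, grid, base) -> Mask:
    """Rasterize lobe polygons into a specimen image laid out like the grid.

    The reference image uses the identity placement: canonical (0, 0) sits at
    image-mm ``base`` so the raster coincides with the atlas raster and
    registration is exactly invertible.
    """
    combined = np.zeros(grid.shape, dtype=bool)
    for poly in polys:
        combined |= rasterize_polygon(poly, grid).pixels
    return Mask(combined, grid.resolution, grid.view)


def _landmarks(view: str, base, pixel_size: float) -> dict:
    skel = load_skeleton_template()
    return {
        name: image_mm_to_px(np.asarray(p, float) + base, pixel_size)
        for name, p in skel.landmarks(view).items()
    }


def reference_specimens(phase: str = "native", n: int = 6,
                        resolution: float = 0.02) -> list:
    """N identical zero-noise reference specimens, pipeline-ready.

    Each record carries the front mask, a single-plane section stack cut
    2 mm below the upper border of the thyroid cartilage, matched landmark
    sidecars, and the phase label (the single plane does not support
    volumetric phase assignment).
    """
    polys = reference_polygons(phase)
    fgrid = front_grid(resolution)
    sgrid = section_grid(resolution)
    front = _image_mask(polys["front"].values(), fgrid, _FRONT_BASE)
    section = _image_mask(polys["section"].values(), sgrid, _SECTION_BASE)
    front_lms = _landmarks("front", _FRONT_BASE, resolution)
    section_lms = _landmarks("section", _SECTION_BASE, resolution)
    from .cohort import phase_slug

    records = []
    for i in range(n):
        sid = f"ref-{phase_slug(phase)}-{i:02d}"
        fm = Mask(front.pixels.copy(), resolution, "front", sid)
        sm = Mask(section.pixels.copy(), resolution, "section", sid)
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                front_mask=fm,
                front_landmarks=dict(front_lms),
                sections=SectionStack(sid, [(REFERENCE_PLANE_DEPTH, sm)], 0.5),
                section_landmarks=dict(section_lms),
                phase=phase,
            )
        )
    return records
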