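"""Canonical cartilage-anchored coordinate frames.

Each specimen photograph or section image is tied to the skeleton of the
laryngeal cartilages through a small set of hand-placed landmarks.  In the
ventral ("front") view the X axis runs along the upper border of the thyroid
cartilage and the Y axis along the anterior middle ridge (the neck midline);
their junction is the origin.  In the transverse-section view the X axis is
parallel to the cricoid lamina through the tangent point on the anterior wall
of the ring, and the Z axis is the perpendicular through that point.

Conventions (fixed here, used everywhere downstream):

* +X points toward the animal's *left* lobe, so the left lobe has positive X.
* +Y points cranially; positions below the upper border have negative Y.
* +Z points dorsally (toward the cricoid lamina); the thyroid lobes sit at
  positive Z behind the anterior tracheal wall.

Image pixel coordinates are converted to a right-handed "image-mm" plane by
``(x_mm, y_mm) = (col * s, -row * s)`` with ``s`` the pixel size in mm/px, so
that rigid (proper) transforms suffice for registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateLandmarksError",
    "CoordinateFrame",
    "CartilageSkeleton",
    "LANDMARK_NAMES",
    "build_front_frame",
    "build_section_frame",
    "load_skeleton_template",
    "canonical_frame",
    "to_canonical",
    "from_canonical",
    "px_to_image_mm",
    "image_mm_to_px",
    "read_landmark_sidecar",
    "write_landmark_sidecar",
]

#: Controlled vocabulary for landmark sidecars.  ``upper_border_1`` lies on the
#: animal's right, ``upper_border_2`` on the animal's left; ``midline_1`` is
#: the cranial midline point and ``midline_2`` the caudal one; ``lamina_1`` is
#: on the animal's right end of the cricoid lamina.
LANDMARK_NAMES = (
    "upper_border_1",
    "upper_border_2",
    "midline_1",
    "midline_2",
    "lamina_1",
    "lamina_2",
    "anterior_tangent",
    "lateral_fossa_L",
    "lateral_fossa_R",
)

_MIN_LINE_ANGLE_DEG = 10.0


class DegenerateLandmarksError(ValueError):
    """Landmarks do not define a usable coordinate frame."""


def px_to_image_mm(p_px, pixel_size: float) -> np.ndarray:
    """Map pixel coordinates (col, row) to the right-handed image-mm plane."""
    p = np.asarray(p_px, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] * pixel_size
    out[..., 1] = -p[..., 1] * pixel_size
    return out


def image_mm_to_px(p_mm, pixel_size: float) -> np.ndarray:
    p = np.asarray(p_mm, dtype=float)
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] / pixel_size
    out[..., 1] = -p[..., 1] / pixel_size
    return out


@dataclass(frozen=True)
class CoordinateFrame:
    """Origin plus orthonormal axes of one view, in the image-mm plane.

    ``second_axis`` is Y for the front view and Z for the section view.
    Axes are unit length, mutually orthogonal and right handed
    (``det [x_axis second_axis] = +1``).
    """

    view: str
    origin: np.ndarray
    x_axis: np.ndarray
    second_axis: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.view not in ("front", "section"):
            raise ValueError(f"unknown view {self.view!r}")
        for name in ("origin", "x_axis", "second_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 2-vector")
            object.__setattr__(self, name, v)
        if abs(np.linalg.norm(self.x_axis) - 1) > 1e-9 or abs(
            np.linalg.norm(self.second_axis) - 1
        ) > 1e-9:
            raise ValueError("axes must be unit length")
        if abs(float(self.x_axis @ self.second_axis)) > 1e-9:
            raise ValueError("axes must be orthogonal")
        det = float(self.x_axis[0] * self.second_axis[1]
                    - self.x_axis[1] * self.second_axis[0])
        if det < 0:
            raise ValueError("frame must be right handed")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def rotation(self) -> np.ndarray:
        """2x2 matrix whose rows project image-mm vectors onto the axes."""
        return np.stack([self.x_axis, self.second_axis])


@dataclass(frozen=True)
class CartilageSkeleton:
    """Packaged landmark template of the laryngeal cartilage skeleton."""

    version: str
    front_landmarks: dict = field(default_factory=dict)
    section_landmarks: dict = field(default_factory=dict)
    front_outlines: dict = field(default_factory=dict)
    section_outlines: dict = field(default_factory=dict)

    def landmarks(self, view: str) -> dict:
        return self.front_landmarks if view == "front" else self.section_landmarks


def _fit_line_tls(points: np.ndarray):
    """Total-least-squares line through >= 2 points.

    Returns (centroid, unit direction).  Direction sign is arbitrary; callers
    orient it.  Raises if the points are (nearly) coincident.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 2:
        raise DegenerateLandmarksError("need at least two 2-D points to fit a line")
    c = pts.mean(axis=0)
    centered = pts - c
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-12:
        raise DegenerateLandmarksError("line points are coincident")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    return c, d / np.linalg.norm(d)


def _intersect_lines(c1, d1, c2, d2) -> np.ndarray:
    a = np.column_stack([d1, -d2])
    try:
        t = np.linalg.solve(a, c2 - c1)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by angle check
        raise DegenerateLandmarksError("landmark lines are parallel") from exc
    return c1 + t[0] * d1


def _rot_minus_90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by -90 degrees (y-up convention)."""
    return np.array([v[1], -v[0]])


def build_front_frame(upper_border_px, midline_px, pixel_size: float) -> CoordinateFrame:
    """Front-view frame from upper-border and midline landmark pixels.

    The Y axis is the total-least-squares midline (the neck middle line is the
    stated reference, so it is kept exact), oriented cranially using the
    ``midline_1`` (cranial) to ``midline_2`` (caudal) ordering.  The X axis is
    the perpendicular through the intersection with the fitted upper-border
    line; the border direction only disambiguates handedness.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    border = px_to_image_mm(np.atleast_2d(upper_border_px), pixel_size)
    midline = px_to_image_mm(np.atleast_2d(midline_px), pixel_size)
    cb, db = _fit_line_tls(border)
    cm, dm = _fit_line_tls(midline)

    angle = np.degrees(np.arccos(min(1.0, abs(float(db @ dm)))))
    if angle < _MIN_LINE_ANGLE_DEG:
        raise DegenerateLandmarksError(
            f"upper border and midline are near-parallel ({angle:.1f} deg < "
            f"{_MIN_LINE_ANGLE_DEG} deg)"
        )
    origin = _intersect_lines(cb, db, cm, dm)

    # orient Y cranially: from the last (caudal) toward the first (cranial) point
    y_dir = midline[0] - midline[-1]
    if np.linalg.norm(y_dir) < 1e-12:
        y_dir = dm
    y_axis = dm if float(dm @ y_dir) >= 0 else -dm
    x_axis = _rot_minus_90(y_axis)
    # the border runs from the animal's right (upper_border_1) to its left
    b_dir = border[-1] - border[0]
    if float(x_axis @ b_dir) < 0:
        raise DegenerateLandmarksError(
            "landmarks imply a mirrored image (upper border direction opposes "
            "the right-handed X axis)"
        )
    return CoordinateFrame("front", origin, x_axis, y_axis, pixel_size)


def build_section_frame(lamina_px, anterior_tangent_px, pixel_size: float) -> CoordinateFrame:
    """Section-view frame from cricoid lamina landmarks and the tangent point.

    X is parallel to the lamina through the anterior tangent point; Z is the
    perpendicular through the same point, oriented dorsally (toward the
    lamina).  The origin is the tangent point.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    lamina = px_to_image_mm(np.atleast_2d(lamina_px), pixel_size)
    origin = px_to_image_mm(np.asarray(anterior_tangent_px, dtype=float), pixel_size)
    cl, dl = _fit_line_tls(lamina)

    v = cl - origin
    perp = v - (v @ dl) * dl
    n = np.linalg.norm(perp)
    if n < 1e-9:
        raise DegenerateLandmarksError("anterior tangent point lies on the lamina line")
    z_axis = perp / n
    x_axis = _rot_minus_90(z_axis)
    l_dir = lamina[-1] - lamina[0]
    if float(x_axis @ l_dir) < 0:
        raise DegenerateLandmarksError(
            "landmarks imply a mirrored section (lamina direction opposes the "
            "right-handed X axis)"
        )
    return CoordinateFrame("section", origin, x_axis, z_axis, pixel_size)


def canonical_frame(view: str) -> CoordinateFrame:
    """The atlas-space template frame: identity axes with the origin at (0, 0)."""
    return CoordinateFrame(
        view, np.zeros(2), np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0
    )


def to_canonical(p_px, frame: CoordinateFrame, pixel_size: float | None = None) -> np.ndarray:
    """Express image pixel coordinates in the frame's canonical mm system."""
    s = frame.pixel_size if pixel_size is None else pixel_size
    p = px_to_image_mm(p_px, s)
    return (p - frame.origin) @ frame.rotation.T


def from_canonical(q_mm, frame: CoordinateFrame, pixel_size: float | None = None) -> np.ndarray:
    """Inverse of :func:`to_canonical`: canonical mm back to image pixels."""
    s = frame.pixel_size if pixel_size is None else pixel_size
    q = np.asarray(q_mm, dtype=float)
    p = q @ frame.rotation + frame.origin
    return image_mm_to_px(p, s)


def load_skeleton_template() -> CartilageSkeleton:
    """Load the packaged cartilage-skeleton landmark template (JSON resource)."""
    raw = json.loads(
        resources.files("thyromap.data").joinpath("skeleton_template.json").read_text()
    )
    to_arr = lambda d: {k: np.asarray(v, dtype=float) for k, v in d.items()}
    return CartilageSkeleton(
        version=raw["version"],
        front_landmarks=to_arr(raw["front_landmarks"]),
        section_landmarks=to_arr(raw["section_landmarks"]),
        front_outlines={k: np.asarray(v, float) for k, v in raw["front_outlines"].items()},
        section_outlines={k: np.asarray(v, float) for k, v in raw["section_outlines"].items()},
    )


def read_landmark_sidecar(path) -> pd.DataFrame:
    """Read a landmark sidecar CSV.

    Columns: specimen_id, view, landmark_name, px_x, px_y, pixel_size_mm.
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "view", "landmark_name", "px_x", "px_y", "pixel_size_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark sidecar missing columns: {sorted(missing)}")
    unknown = set(df["landmark_name"]) - set(LANDMARK_NAMES)
    if unknown:
        raise ValueError(f"unknown landmark names: {sorted(unknown)}")
    return df


def write_landmark_sidecar(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def sidecar_landmarks(df: pd.DataFrame, specimen_id: str, view: str):
    """Extract one specimen/view from a sidecar as (dict name -> (px_x, px_y), pixel_size)."""
    sub = df[(df["specimen_id"] == specimen_id) & (df["view"] == view)]
    if sub.empty:
        raise KeyError(f"no landmarks for specimen {specimen_id!r} view {view!r}")
    sizes = sub["pixel_size_mm"].unique()
    if len(sizes) != 1:
        raise ValueError("inconsistent pixel sizes within one specimen/view")
    lms = {
        row.landmark_name: np.array([row.px_x, row.px_y])
        for row in sub.itertuples()
    }
    return lms, float(sizes[0])
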