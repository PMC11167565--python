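"""Landmark-frame rigid registration onto the canonical skeleton frame.

Aligning a specimen to the template reduces to making the two landmark-derived
coordinate frames coincide, which is closed form: the transform carries the
specimen frame's origin onto the template origin and its axes onto the
template axes.  Default mode is rigid (no scaling) because photographs were
taken at a fixed shooting distance; similarity mode scales by the ratio of
the lateral-fossa spacing for uncalibrated inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frames import CoordinateFrame, image_mm_to_px, px_to_image_mm
from .raster import AtlasGrid, Mask

__all__ = [
    "RigidTransform",
    "estimate_transform",
    "apply_transform",
    "residual_error",
]


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform q = scale * R(angle) p + (tx, ty), mm to mm.

    Maps specimen image-mm coordinates into the canonical (template) frame.
    ``scale`` defaults to 1 (pure rigid).
    """

    angle: float
    tx: float
    ty: float
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, pts) -> np.ndarray:
        p = np.asarray(pts, dtype=float)
        return self.scale * p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        inv_r = self.rotation.T
        t = -(inv_r @ self.translation) / self.scale
        return RigidTransform(-self.angle, t[0], t[1], 1.0 / self.scale)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        r = self.rotation @ other.rotation
        t = self.scale * self.rotation @ other.translation * 1.0 + self.translation
        angle = float(np.arctan2(r[1, 0], r[0, 0]))
        return RigidTransform(angle, t[0], t[1], self.scale * other.scale)


def estimate_transform(
    specimen_frame: CoordinateFrame,
    template_frame: CoordinateFrame,
    mode: str = "rigid",
    specimen_landmarks: dict | None = None,
    template_landmarks: dict | None = None,
) -> RigidTransform:
    """Closed-form transform aligning the specimen frame onto the template frame.

    ``mode='similarity'`` additionally scales by the ratio of the lateral-fossa
    spacing (template over specimen); both landmark dicts must then contain
    ``lateral_fossa_L`` and ``lateral_fossa_R``.  Specimen landmarks are in
    image pixels (converted with the specimen frame's pixel size), template
    landmarks in canonical mm.
    """
    if specimen_frame.view != template_frame.view:
        raise ValueError(
            f"view mismatch: {specimen_frame.view!r} vs {template_frame.view!r}"
        )
    if mode not in ("rigid", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")

    scale = 1.0
    if mode == "similarity":
        if not (specimen_landmarks and template_landmarks):
            raise ValueError("similarity mode needs specimen and template landmarks")
        try:
            s_pair = [specimen_landmarks["lateral_fossa_L"], specimen_landmarks["lateral_fossa_R"]]
            t_pair = [template_landmarks["lateral_fossa_L"], template_landmarks["lateral_fossa_R"]]
        except KeyError as exc:
            raise ValueError("similarity mode needs both lateral fossa landmarks") from exc
        s_mm = px_to_image_mm(np.asarray(s_pair, float), specimen_frame.pixel_size)
        d_spec = float(np.linalg.norm(s_mm[0] - s_mm[1]))
        d_tmpl = float(np.linalg.norm(np.asarray(t_pair[0], float) - np.asarray(t_pair[1], float)))
        if d_spec < 1e-12:
            raise ValueError("specimen lateral fossa landmarks coincide")
        scale = d_tmpl / d_spec

    # rows of A project ambient vectors onto frame axes; columns of B embed them
    a_spec = specimen_frame.rotation
    b_tmpl = template_frame.rotation.T
    r = b_tmpl @ a_spec
    angle = float(np.arctan2(r[1, 0], r[0, 0]))
    t = template_frame.origin - scale * r @ specimen_frame.origin
    return RigidTransform(angle, float(t[0]), float(t[1]), scale)


def apply_transform(m: Mask, t: RigidTransform, grid: AtlasGrid) -> Mask:
    """Resample a raw image mask onto the atlas grid through ``t``.

    Nearest-neighbor on the inverse transform: each atlas cell center is
    pulled back into the image and takes the value of the pixel it lands in,
    preserving the binary nature of the mask.
    """
    if m.view != grid.view:
        raise ValueError(f"view mismatch: mask {m.view!r} vs grid {grid.view!r}")
    xx, ss = grid.cell_centers()
    pts = np.column_stack([xx.ravel(), ss.ravel()])
    back = t.inverse().apply(pts)
    px = image_mm_to_px(back, m.pixel_size)
    col = np.floor(px[:, 0]).astype(int)
    row = np.floor(px[:, 1]).astype(int)
    h, w = m.pixels.shape
    ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = m.pixels[row[ok], col[ok]]
    out = out.reshape(grid.shape)
    if m.pixels.any() and not out.any():
        warnings.warn(
            f"transformed mask {m.specimen_id!r} falls wholly outside the atlas grid",
            stacklevel=2,
        )
    return Mask(out, grid.resolution, grid.view, m.specimen_id, grid)


def residual_error(t: RigidTransform, specimen_landmarks, template_landmarks) -> float:
    """RMS distance (mm) between transformed specimen and template landmarks.

    Landmarks may be dicts (matched by shared keys) or aligned (N, 2) arrays.
    Specimen landmarks are in image-mm, template landmarks in canonical mm.
    """
    if isinstance(specimen_landmarks, dict) and isinstance(template_landmarks, dict):
        keys = sorted(set(specimen_landmarks) & set(template_landmarks))
        if not keys:
            raise ValueError("no corresponding landmark pairs")
        s = np.array([specimen_landmarks[k] for k in keys], dtype=float)
        q = np.array([template_landmarks[k] for k in keys], dtype=float)
    else:
        s = np.atleast_2d(np.asarray(specimen_landmarks, dtype=float))
        q = np.atleast_2d(np.asarray(template_landmarks, dtype=float))
        if s.shape != q.shape or s.size == 0:
            raise ValueError("landmark arrays must be non-empty and aligned")
    d = t.apply(s) - q
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
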