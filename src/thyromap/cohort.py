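"""Seeded synthetic specimen generator with known ground truth.

The generator stands in for the study animals: per phase it draws a target
volume from a truncated-normal phase distribution, solves two
superellipsoidal lateral lobes to match that volume exactly, and renders
the observations the real protocol produces — a ventral ("front") photograph
mask, a serial transverse section stack at 0.5 mm spacing, landmark sidecars
jittered with the same placement transform as the masks (so registration can
undo it), and a paired in-vivo/ex-vivo rendering with independent small
misalignments and boundary noise.

Lobe model
----------
Each lobe is a superellipsoid (default exponent 2, an ellipsoid) with
semi-axes (W/2 mediolateral, L/2 craniocaudal, T/2 anteroposterior) plus a
mediolateral shear dx/dy so the lobe runs obliquely: near the midline at its
cranial (proximal) end and lateral at its caudal (distal) end, as the lobes
do in the ventral view.  Shear preserves the analytic volume, the centroid,
and the per-level width.

Calibration anchors (shape proportions) come from the printed native lobe
(2.0 long x 0.6 wide x 0.8 thick mm, medial edge ~0.5 mm, centered at the
cricoid-ring level y = -2) and the largest phase (4.0 x 1.6 x 1.6 mm, medial
edge ~0.1 mm, center 0.5 mm lower); between them the proportions are
interpolated in volume and rescaled uniformly so the analytic volume equals
the drawn target.  Growth therefore extends the lobes laterally and caudally
in the front view (the center of gravity moves down) while the section-plane
center stays nearly fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import gamma

from .frames import image_mm_to_px, load_skeleton_template
from .raster import AtlasGrid, Mask, SectionStack, front_grid, section_grid
from .register import RigidTransform
from .volumetry import PHASES, plan_sections

__all__ = [
    "LobeParams",
    "SyntheticSpecimen",
    "CohortConfig",
    "PhaseVolumeDist",
    "generate_specimen",
    "render_views",
    "generate_cohort",
    "superellipsoid_volume",
    "superellipse_area",
    "ellipsoid_phantom_stack",
    "phase_slug",
]

# base placement of the canonical origin inside the synthetic images, chosen
# so that an unjittered image raster coincides with the default atlas grids
_FRONT_BASE = np.array([4.0, -1.0])
_SECTION_BASE = np.array([3.0, -3.0])


def superellipsoid_volume(a: float, b: float, c: float, p: float = 2.0) -> float:
    """Analytic volume of |x/a|^p + |y/b|^p + |z/c|^p <= 1 (8abc pi/6-like form)."""
    g = gamma(1.0 + 1.0 / p)
    return float(8.0 * a * b * c * g**3 / gamma(1.0 + 3.0 / p))


def superellipse_area(a: float, c: float, p: float = 2.0) -> float:
    """Analytic area of |x/a|^p + |z/c|^p <= 1."""
    g = gamma(1.0 + 1.0 / p)
    return float(4.0 * a * c * g**2 / gamma(1.0 + 2.0 / p))


@dataclass(frozen=True)
class LobeParams:
    """Geometry of one lateral lobe in canonical mm coordinates."""

    side: str  # "left" (+X) or "right" (-X)
    length: float  # craniocaudal, mm
    width: float  # mediolateral, mm
    thickness: float  # anteroposterior, mm
    medial_offset: float  # |x| of the medial edge at the lobe's central level
    cranial_offset: float  # canonical Y of the lobe's cranial tip
    center_z: float = 1.05
    shear: float = 0.2  # lateral shift (mm) per mm caudal
    exponent: float = 2.0

    def __post_init__(self):
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("lobe dimensions must be positive")
        if self.medial_offset < 0:
            raise ValueError("medial offset must be non-negative")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def sign(self) -> float:
        return 1.0 if self.side == "left" else -1.0

    @property
    def center_x(self) -> float:
        return self.sign * (self.medial_offset + self.width / 2.0)

    @property
    def center_y(self) -> float:
        return self.cranial_offset - self.length / 2.0

    @property
    def centroid(self) -> tuple:
        return (self.center_x, self.center_y, self.center_z)

    @property
    def volume_mm3(self) -> float:
        return superellipsoid_volume(
            self.width / 2.0, self.length / 2.0, self.thickness / 2.0, self.exponent
        )

    # --- analytic occupancy -------------------------------------------------
    def _axis_center_x(self, y) -> np.ndarray:
        """Mediolateral center of the lobe at craniocaudal level y (sheared)."""
        return self.center_x + self.sign * self.shear * (self.center_y - np.asarray(y))

    def silhouette(self, x, y) -> np.ndarray:
        """Ventral-view occupancy (projection over Z) at canonical (x, y)."""
        p = self.exponent
        u = np.abs(x - self._axis_center_x(y)) / (self.width / 2.0)
        v = np.abs(np.asarray(y) - self.center_y) / (self.length / 2.0)
        return u**p + v**p <= 1.0

    def section_scale(self, y: float) -> float:
        """In-plane semi-axis scale factor at level y (0 outside the lobe)."""
        v = abs(y - self.center_y) / (self.length / 2.0)
        if v >= 1.0:
            return 0.0
        return float((1.0 - v**self.exponent) ** (1.0 / self.exponent))

    def section_occupancy(self, x, z, y: float) -> np.ndarray:
        s = self.section_scale(y)
        if s == 0.0:
            return np.zeros(np.broadcast(x, z).shape, dtype=bool)
        p = self.exponent
        u = np.abs(x - self._axis_center_x(y)) / (self.width / 2.0 * s)
        w = np.abs(z - self.center_z) / (self.thickness / 2.0 * s)
        return u**p + w**p <= 1.0

    def section_area(self, y: float) -> float:
        s = self.section_scale(y)
        return superellipse_area(self.width / 2.0 * s, self.thickness / 2.0 * s, self.exponent)


@dataclass(frozen=True)
class PhaseVolumeDist:
    """Truncated-normal volume distribution of one phase (mm³)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        if not self.lo < self.hi:
            raise ValueError("empty support")
        for _ in range(10_000):
            v = rng.normal(self.mean, self.sd) if self.sd > 0 else self.mean
            if self.lo < v <= self.hi:
                return float(v)
        raise ValueError(
            f"could not draw a volume inside ({self.lo}, {self.hi}] from "
            f"N({self.mean}, {self.sd}²)"
        )


#: Phase volume distributions matching the size bins: native thyroids span
#: 2-3 mm³; each immunized phase is centered in its bin with an SD that keeps
#: essentially all mass inside.
DEFAULT_PHASE_DISTS = {
    "native": PhaseVolumeDist(2.5, 0.3, 2.0, 3.0),
    "T03-06": PhaseVolumeDist(4.5, 0.9, 3.0, 6.0),
    "T06-09": PhaseVolumeDist(7.5, 0.9, 6.0, 9.0),
    "T09-12": PhaseVolumeDist(10.5, 0.9, 9.0, 12.0),
    "T12-15": PhaseVolumeDist(13.5, 0.9, 12.0, 15.0),
    "T>15": PhaseVolumeDist(17.5, 2.0, 15.0, 24.0),
}

# shape anchors: (volume, length, width, thickness, center_y) — printed native
# and largest-phase lobe geometry; the mediolateral lobe centers are held
# fixed (the section-plane center of gravity stays put during enlargement)
_ANCHOR_SMALL = (2.5, 2.0, 0.6, 0.8, -2.0)
_ANCHOR_LARGE = (17.5, 4.0, 1.6, 1.6, -2.5)
_CENTER_X = {"left": 1.0, "right": 0.9}
_CENTER_Z = {"left": 1.1, "right": 1.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Jitter sigmas emulate specimen placement variability between photographs;
    the pair sigmas are the residual in-vivo/ex-vivo misalignment left after
    registration; boundary noise is a random one-pixel dilation/erosion of the
    rendered outline.
    """

    n_per_phase: int = 6
    phases: tuple = PHASES
    phase_dists: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_DISTS))
    jitter_rot_deg: float = 2.0
    jitter_trans_mm: float = 0.1
    pair_rot_deg: float = 1.0
    pair_trans_mm: float = 0.1
    boundary_noise_px: int = 1
    shear: float = 0.2
    exponent: float = 2.0
    section_interval: float = 0.5
    section_span: float = 6.5
    image_resolution: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("jitter_rot_deg", "jitter_trans_mm", "pair_rot_deg",
                     "pair_trans_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_per_phase < 1:
            raise ValueError("n_per_phase must be >= 1")

    def zero_noise(self) -> "CohortConfig":
        """Copy with all jitter and noise switched off (parameter-recovery runs)."""
        return replace(
            self, jitter_rot_deg=0.0, jitter_trans_mm=0.0, pair_rot_deg=0.0,
            pair_trans_mm=0.0, boundary_noise_px=0,
        )


@dataclass(frozen=True)
class SyntheticSpecimen:
    """Ground truth of one generated animal."""

    specimen_id: str
    phase: str
    left: LobeParams
    right: LobeParams
    true_volume_mm3: float
    front_jitter: RigidTransform
    section_jitter: RigidTransform
    pair_rot_deg: float
    pair_trans_mm: float
    boundary_noise_px: int
    seed: int

    def __post_init__(self):
        analytic = self.left.volume_mm3 + self.right.volume_mm3
        if abs(analytic - self.true_volume_mm3) > 1e-9:
            raise ValueError("true volume inconsistent with analytic lobe volume")

    @property
    def lobes(self) -> tuple:
        return (self.left, self.right)

    @property
    def true_centroids(self) -> dict:
        return {lobe.side: lobe.centroid for lobe in self.lobes}


def _solve_lobes(volume: float, cfg: CohortConfig) -> tuple:
    """Lobe geometry matching a target total volume exactly.

    Proportions interpolate linearly in volume between the printed anchors,
    then all three dimensions are rescaled by a common cube-root factor so
    each lobe's analytic volume is half the target.
    """
    v0, *small = _ANCHOR_SMALL
    v1, *large = _ANCHOR_LARGE
    t = float(np.clip((volume - v0) / (v1 - v0), -0.25, 1.5))
    length, width, thick, center_y = (1 - t) * np.array(small) + t * np.array(large)
    base = superellipsoid_volume(width / 2, length / 2, thick / 2, cfg.exponent)
    f = (volume / 2.0 / base) ** (1.0 / 3.0)
    length, width, thick = f * length, f * width, f * thick
    lobes = []
    for side in ("left", "right"):
        lobes.append(
            LobeParams(
                side=side,
                length=length,
                width=width,
                thickness=thick,
                medial_offset=max(_CENTER_X[side] - width / 2.0, 0.02),
                cranial_offset=center_y + length / 2.0,
                center_z=_CENTER_Z[side],
                shear=cfg.shear,
                exponent=cfg.exponent,
            )
        )
    return tuple(lobes)


def _draw_jitter(rng: np.random.Generator, rot_deg: float, trans_mm: float,
                 base: np.ndarray) -> RigidTransform:
    angle = np.deg2rad(rng.normal(0.0, rot_deg)) if rot_deg > 0 else 0.0
    t = rng.normal(0.0, trans_mm, size=2) if trans_mm > 0 else np.zeros(2)
    return RigidTransform(float(angle), float(base[0] + t[0]), float(base[1] + t[1]))


def generate_specimen(cfg: CohortConfig, phase: str, seed: int) -> SyntheticSpecimen:
    """Deterministically generate one specimen for a phase from a seed."""
    if phase not in cfg.phase_dists:
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(seed)
    volume = cfg.phase_dists[phase].draw(rng)
    left, right = _solve_lobes(volume, cfg)
    front_jitter = _draw_jitter(rng, cfg.jitter_rot_deg, cfg.jitter_trans_mm, _FRONT_BASE)
    section_jitter = _draw_jitter(rng, cfg.jitter_rot_deg, cfg.jitter_trans_mm, _SECTION_BASE)
    return SyntheticSpecimen(
        specimen_id=f"{phase_slug(phase)}-s{seed % 10_000_000:07d}",
        phase=phase,
        left=left,
        right=right,
        true_volume_mm3=left.volume_mm3 + right.volume_mm3,
        front_jitter=front_jitter,
        section_jitter=section_jitter,
        pair_rot_deg=cfg.pair_rot_deg,
        pair_trans_mm=cfg.pair_trans_mm,
        boundary_noise_px=cfg.boundary_noise_px,
        seed=int(seed),
    )


def _render_canonical(lobes, grid: AtlasGrid, jitter: RigidTransform,
                      plane_y: float | None = None) -> np.ndarray:
    """Occupancy raster of the lobes on an image grid placed by ``jitter``.

    ``jitter`` maps canonical mm to image-mm; the raster is evaluated by
    pulling every cell center back into canonical coordinates.
    """
    res = grid.resolution
    cols = (np.arange(grid.n_cols) + 0.5) * res
    rows = -(np.arange(grid.n_rows) + 0.5) * res
    xx, yy = np.meshgrid(cols, rows)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    q = jitter.inverse().apply(pts)
    qx, qy = q[:, 0], q[:, 1]
    out = np.zeros(len(pts), dtype=bool)
    for lobe in lobes:
        if plane_y is None:
            out |= lobe.silhouette(qx, qy)
        else:
            out |= lobe.section_occupancy(qx, qy, plane_y)
    return out.reshape(grid.shape)


def _landmark_px(names, view: str, jitter: RigidTransform, pixel_size: float) -> dict:
    skel = load_skeleton_template()
    lms = skel.landmarks(view)
    return {
        name: image_mm_to_px(jitter.apply(lms[name]), pixel_size)
        for name in names
    }


def _boundary_noise(pixels: np.ndarray, rng: np.random.Generator, amp_px: int) -> np.ndarray:
    if amp_px <= 0:
        return pixels
    k = int(rng.integers(-amp_px, amp_px + 1))
    if k == 0:
        return pixels
    op = ndimage.binary_dilation if k > 0 else ndimage.binary_erosion
    return op(pixels, iterations=abs(k))


def render_views(s: SyntheticSpecimen, *, front: AtlasGrid | None = None,
                 section: AtlasGrid | None = None, interval: float = 0.5,
                 span: float = 6.5, image_resolution: float = 0.02) -> dict:
    """Render all observations of one specimen; deterministic given the specimen.

    Returns a dict with the jittered front Mask and landmark pixels, the
    jittered SectionStack and section landmarks, and the in-vivo/ex-vivo pair
    on the atlas front grid.
    """
    rng = np.random.default_rng(np.random.SeedSequence((s.seed, 0xC0)))
    fgrid = front or front_grid(image_resolution)
    sgrid = section or section_grid(image_resolution)

    front_px = _render_canonical(s.lobes, fgrid, s.front_jitter)
    front_mask = Mask(front_px, fgrid.resolution, "front", s.specimen_id)
    front_lms = _landmark_px(
        ("upper_border_1", "upper_border_2", "midline_1", "midline_2",
         "lateral_fossa_L", "lateral_fossa_R"),
        "front", s.front_jitter, fgrid.resolution,
    )

    planes = []
    for depth in plan_sections(span, interval):
        y = -float(depth)
        px = _render_canonical(s.lobes, sgrid, s.section_jitter, plane_y=y)
        planes.append((float(depth), Mask(px, sgrid.resolution, "section", s.specimen_id)))
    nonempty = [i for i, (_, m) in enumerate(planes) if m.pixels.any()]
    if nonempty:  # stop cutting once the tissue disappears, as in the protocol
        planes = planes[nonempty[0]:nonempty[-1] + 1]
    else:
        warnings.warn(f"{s.specimen_id}: no section plane hits the thyroid", stacklevel=2)
        planes = planes[:1]
    stack = SectionStack(s.specimen_id, planes, interval)
    section_lms = _landmark_px(
        ("lamina_1", "lamina_2", "anterior_tangent"),
        "section", s.section_jitter, sgrid.resolution,
    )

    pair = []
    atlas = front_grid(image_resolution)
    for _ in range(2):
        mis = _draw_jitter(rng, s.pair_rot_deg, s.pair_trans_mm, np.array([4.0, -1.0]))
        px = _render_canonical(s.lobes, atlas, mis)
        px = _boundary_noise(px, rng, s.boundary_noise_px)
        pair.append(Mask(px, atlas.resolution, "front", s.specimen_id, atlas))

    return {
        "front": front_mask,
        "front_landmarks": front_lms,
        "sections": stack,
        "section_landmarks": section_lms,
        "pair": tuple(pair),
    }


def phase_slug(phase: str) -> str:
    """Filesystem-safe short name of a phase label."""
    return phase.replace(">", "gt").replace("-", "")


def child_seed(master_seed: int, phase_index: int, specimen_index: int) -> int:
    """Reproducible per-specimen seed, independent of generation order."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(phase_index, specimen_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(cfg: CohortConfig) -> tuple:
    """Generate the full cohort: (list of SyntheticSpecimen, manifest DataFrame)."""
    import pandas as pd

    specimens = []
    rows = []
    for pi, phase in enumerate(cfg.phases):
        for i in range(cfg.n_per_phase):
            seed = child_seed(cfg.seed, pi, i)
            s = generate_specimen(cfg, phase, seed)
            s = replace(s, specimen_id=f"{phase_slug(phase)}-{i:02d}")
            specimens.append(s)
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "phase": phase,
                    "seed": seed,
                    "true_volume_mm3": s.true_volume_mm3,
                    "lobe_length_mm": s.left.length,
                    "lobe_width_mm": s.left.width,
                    "lobe_thickness_mm": s.left.thickness,
                }
            )
    return specimens, pd.DataFrame(rows)


def ellipsoid_phantom_stack(
    semi_axes=(1.0, 0.3, 0.4),
    interval: float = 0.05,
    *,
    offset_shift: float = 0.0,
    resolution: float = 0.005,
    exponent: float = 2.0,
) -> tuple:
    """Analytic (super)ellipsoid phantom sectioned into a SectionStack.

    Semi-axes are (mediolateral a, craniocaudal b, anteroposterior c).
    ``offset_shift`` slides the cutting lattice within one interval.  Returns
    ``(stack, analytic_volume)`` — the independent oracle for Cavalieri tests.
    """
    a, b, c = semi_axes
    margin = 2 * resolution
    grid = AtlasGrid("section", (-a - margin, a + margin), (-c - margin, c + margin),
                     resolution)
    xx, zz = grid.cell_centers()
    center_depth = b + interval  # keep all offsets positive
    depths = offset_shift + np.arange(
        int(np.ceil(2 * (b + interval) / interval)) + 1
    ) * interval
    p = exponent
    planes = []
    for d in depths:
        dy = d - center_depth
        v = abs(dy) / b
        if v >= 1.0:
            px = np.zeros(grid.shape, dtype=bool)
        else:
            s = (1.0 - v**p) ** (1.0 / p)
            px = (np.abs(xx) / (a * s)) ** p + (np.abs(zz) / (c * s)) ** p <= 1.0
        planes.append((float(d), Mask(px, resolution, "section", "phantom", grid)))
    stack = SectionStack("phantom", planes, interval)
    return stack, superellipsoid_volume(a, b, c, p)
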