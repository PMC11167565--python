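"""End-to-end orchestration: register → volumetry → atlas → topography → validation.

The pipeline consumes specimen records (front mask + landmarks, section stack
+ landmarks, optional in-vivo/ex-vivo pair), registers everything into the
canonical frame, estimates volumes and phases, subsamples each phase to a
fixed N, builds per-phase incidence maps in both views, extracts threshold
regions, lobe extents and 3-D central points, merges the phase topography,
and runs the pairwise validation.  All randomness is seeded and every output
row is traceable to a specimen id; a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .atlas import (
    build_incidence_map,
    central_point,
    merge_topography,
    split_lobes,
    threshold_region,
)
from .cohort import SyntheticSpecimen, render_views
from .frames import (
    build_front_frame,
    build_section_frame,
    canonical_frame,
    load_skeleton_template,
    px_to_image_mm,
)
from .raster import (
    AtlasGrid,
    Mask,
    SectionStack,
    front_grid,
    read_mask,
    section_grid,
    write_mask,
)
from .register import apply_transform, estimate_transform, residual_error
from .validation import cohort_validation
from .volumetry import PHASES, VolumeRecord, assign_phase, cavalieri_volume

__all__ = [
    "RunConfig",
    "SpecimenRecord",
    "RunReport",
    "run_pipeline",
    "subsample_phase",
    "records_from_specimens",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger("thyromap")


@dataclass
class SpecimenRecord:
    """One specimen's observations, pre-registration."""

    specimen_id: str
    front_mask: Mask | None = None
    front_landmarks: dict | None = None
    sections: SectionStack | None = None
    section_landmarks: dict | None = None
    pair: tuple | None = None
    phase: str | None = None  # known phase overrides the volume-derived one


@dataclass
class RunConfig:
    """Pipeline parameters; defaults reproduce the study protocol."""

    taus: tuple = (0.5, 1.0)
    phase_n: int = 6
    subsample_seed: int = 0
    mode: str = "rigid"
    grid_resolution: float = 0.02
    section_plane_y: float = -2.0  # cricoid-ring level, 2 mm below the upper border
    out_dir: str | None = None
    figures: bool = False

    def __post_init__(self):
        if not all(0 < t <= 1 for t in self.taus):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.phase_n < 1:
            raise ValueError("phase_n must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    volumes: pd.DataFrame
    transforms: pd.DataFrame
    selections: dict
    incidence: dict  # (phase, view) -> IncidenceMap
    regions: dict  # (phase, view, tau) -> Region
    central_points: pd.DataFrame
    extents: pd.DataFrame
    topographies: dict  # (view, tau) -> Topography
    validation: dict | None
    manifest: dict


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def subsample_phase(specimen_ids, n: int = 6, seed: int = 0) -> list:
    """Seeded uniform subsample without replacement; all kept if fewer than n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = sorted(specimen_ids)
    if len(ids) <= n:
        if len(ids) < n:
            warnings.warn(
                f"only {len(ids)} specimens available for a subsample of {n}",
                stacklevel=2,
            )
        return ids
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(pick)]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return inner
    return wrap


@_stage("register")
def _register_record(rec: SpecimenRecord, cfg: RunConfig, fgrid, sgrid, skel):
    """Register one specimen's front mask and section stack onto the atlas grids."""
    out = {"front": None, "sections": None}
    rows = []
    kw = {}
    if cfg.mode == "similarity":
        kw["template_landmarks"] = skel.front_landmarks
    if rec.front_mask is not None:
        lms = rec.front_landmarks
        frame = build_front_frame(
            [lms["upper_border_1"], lms["upper_border_2"]],
            [lms["midline_1"], lms["midline_2"]],
            rec.front_mask.pixel_size,
        )
        t = estimate_transform(
            frame, canonical_frame("front"), cfg.mode,
            specimen_landmarks=lms if cfg.mode == "similarity" else None, **kw,
        )
        out["front"] = apply_transform(rec.front_mask, t, fgrid)
        spec_mm = {
            k: px_to_image_mm(np.asarray(v, float), rec.front_mask.pixel_size)
            for k, v in lms.items()
            if k in skel.front_landmarks
        }
        resid = residual_error(t, spec_mm, skel.front_landmarks)
        rows.append((rec.specimen_id, "front", t, resid))
    if rec.sections is not None:
        lms = rec.section_landmarks
        s = rec.sections.masks[0].pixel_size
        frame = build_section_frame(
            [lms["lamina_1"], lms["lamina_2"]], lms["anterior_tangent"], s
        )
        t = estimate_transform(frame, canonical_frame("section"), "rigid")
        planes = [
            (off, apply_transform(m, t, sgrid)) for off, m in rec.sections.planes
        ]
        out["sections"] = SectionStack(rec.specimen_id, planes, rec.sections.interval)
        spec_mm = {
            k: px_to_image_mm(np.asarray(v, float), s)
            for k, v in lms.items()
            if k in skel.section_landmarks
        }
        resid = residual_error(t, spec_mm, skel.section_landmarks)
        rows.append((rec.specimen_id, "section", t, resid))
    return out, rows


def run_pipeline(records, config: RunConfig | None = None) -> RunReport:
    """Run the full analysis over a list of :class:`SpecimenRecord`."""
    cfg = config or RunConfig()
    records = list(records)
    if not records:
        raise PipelineError("[input] no specimens")
    skel = load_skeleton_template()
    fgrid = front_grid(cfg.grid_resolution)
    sgrid = section_grid(cfg.grid_resolution)

    # -- registration --------------------------------------------------------
    registered = {}
    t_rows = []
    for rec in records:
        out, rows = _register_record(rec, cfg, fgrid, sgrid, skel)
        registered[rec.specimen_id] = out
        for sid, view, t, resid in rows:
            t_rows.append(
                {
                    "specimen_id": sid,
                    "view": view,
                    "angle_deg": float(np.degrees(t.angle)),
                    "tx_mm": t.tx,
                    "ty_mm": t.ty,
                    "scale": t.scale,
                    "residual_mm": resid,
                }
            )
    transforms = pd.DataFrame(t_rows)
    log.info("registered %d specimens", len(records))

    # -- volumetry & phase assignment ---------------------------------------
    v_rows = []
    phase_of = {}
    for rec in records:
        if rec.sections is not None:
            vol = cavalieri_volume(rec.sections)
            n_sec = len(rec.sections)
            interval = rec.sections.interval
        else:
            vol, n_sec, interval = float("nan"), 0, float("nan")
        phase = rec.phase if rec.phase is not None else assign_phase(vol)
        phase_of[rec.specimen_id] = phase
        v_rows.append(
            {
                "specimen_id": rec.specimen_id,
                "n_sections": n_sec,
                "interval_mm": interval,
                "volume_mm3": vol,
                "phase": phase,
            }
        )
    volumes = pd.DataFrame(v_rows)

    # -- per-phase subsample and incidence maps ------------------------------
    by_phase = {}
    for rec in records:
        by_phase.setdefault(phase_of[rec.specimen_id], []).append(rec.specimen_id)
    selections = {}
    incidence = {}
    rec_by_id = {r.specimen_id: r for r in records}
    for pi, phase in enumerate(PHASES):
        if phase not in by_phase:
            continue
        chosen = subsample_phase(by_phase[phase], cfg.phase_n, cfg.subsample_seed + pi)
        selections[phase] = chosen
        fronts = [registered[sid]["front"] for sid in chosen
                  if registered[sid]["front"] is not None]
        if fronts:
            incidence[(phase, "front")] = build_incidence_map(fronts, phase)
        sections = []
        for sid in chosen:
            stack = registered[sid]["sections"]
            if stack is None or len(stack) == 0:
                continue
            ys = stack.plane_y()
            sections.append(stack.masks[int(np.argmin(np.abs(ys - cfg.section_plane_y)))])
        if sections:
            incidence[(phase, "section")] = build_incidence_map(sections, phase)

    # -- threshold regions, extents, central points --------------------------
    regions = {}
    e_rows, c_rows = [], []
    from .atlas import region_extents  # local import keeps module init light

    for (phase, view), imap in incidence.items():
        for tau in cfg.taus:
            region = threshold_region(imap, tau)
            regions[(phase, view, tau)] = region
            if region.is_empty:
                continue
            for lobe_region in split_lobes(region):
                if lobe_region.is_empty:
                    continue
                row = {"phase": phase, "view": view, "tau": tau,
                       "lobe": lobe_region.lobe}
                row.update(region_extents(lobe_region))
                e_rows.append(row)
    for phase in PHASES:
        key = (phase, "section", 1.0)
        if key not in regions or regions[key].is_empty:
            continue
        for lobe_region in split_lobes(regions[key]):
            if lobe_region.is_empty:
                continue
            front_key = (phase, "front", 1.0)
            front_lobe = None
            if front_key in regions and not regions[front_key].is_empty:
                fl, fr = split_lobes(regions[front_key])
                front_lobe = fl if lobe_region.lobe == "left" else fr
            cp = central_point(front_lobe, lobe_region, cfg.section_plane_y,
                               lobe_region.lobe)
            c_rows.append({"phase": phase, "lobe": cp.lobe,
                           "X": cp.x, "Y": cp.y, "Z": cp.z})
    extents = pd.DataFrame(e_rows)
    central_points = pd.DataFrame(c_rows)

    # -- topography ----------------------------------------------------------
    topographies = {}
    for view in ("front", "section"):
        maps = [incidence[k] for k in incidence if k[1] == view]
        if not maps:
            continue
        for tau in cfg.taus:
            topo, _ = merge_topography(maps, tau)
            topographies[(view, tau)] = topo

    # -- validation ----------------------------------------------------------
    validation = None
    pairs = [r.pair for r in records if r.pair is not None]
    if len(pairs) >= 2:
        validation = cohort_validation(pairs)
        log.info(
            "validation: mean overlap rate %.3f over %d pairs",
            validation["summary"]["mean_rate"], len(pairs),
        )

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "version": _pkg_version,
        "n_specimens": len(records),
        "selections": selections,
    }
    report = RunReport(volumes, transforms, selections, incidence, regions,
                       central_points, extents, topographies, validation, manifest)
    if cfg.out_dir:
        _write_report(report, cfg)
    return report


def _write_report(report: RunReport, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.volumes.to_csv(out / "volumes.csv", index=False)
    report.transforms.to_csv(out / "transforms.csv", index=False)
    report.extents.to_csv(out / "extents.csv", index=False)
    report.central_points.to_csv(out / "central_points.csv", index=False)
    if report.validation is not None:
        report.validation["pairs"].to_csv(out / "validation.csv", index=False)
        (out / "validation_summary.json").write_text(
            json.dumps(report.validation["summary"], indent=2)
        )
    (out / "run_manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=str)
    )
    import tifffile

    for (phase, view), imap in report.incidence.items():
        n = imap.n_specimens
        arr = np.round(imap.values * 255).astype(np.uint8)
        tifffile.imwrite(
            out / f"incidence_{view}_{_slug(phase)}.tif", arr,
            description=json.dumps({"n_specimens": n, "scale": "k/N * 255"}),
        )
    if cfg.figures:
        from .plot import plot_topography

        for (view, tau), topo in report.topographies.items():
            fig = plot_topography(topo)
            fig.savefig(out / f"topography_{view}_tau{int(tau * 100)}.png", dpi=150)
    log.info("wrote outputs to %s", out)


def _slug(phase: str) -> str:
    return phase.replace(">", "gt").replace("-", "")


# --- cohort construction and disk round trip -------------------------------

def records_from_specimens(specimens, *, interval: float = 0.5,
                           image_resolution: float = 0.02,
                           with_pairs: bool = True) -> list:
    """Render synthetic specimens into pipeline-ready records."""
    records = []
    for s in specimens:
        views = render_views(s, interval=interval, image_resolution=image_resolution)
        records.append(
            SpecimenRecord(
                specimen_id=s.specimen_id,
                front_mask=views["front"],
                front_landmarks=views["front_landmarks"],
                sections=views["sections"],
                section_landmarks=views["section_landmarks"],
                pair=views["pair"] if with_pairs else None,
                phase=None,
            )
        )
    return records


def write_cohort(records, out_dir, ground_truth: pd.DataFrame | None = None) -> None:
    """Write a cohort directory: PNG masks, manifest CSV, landmark sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_rows, l_rows = [], []

    def add_landmarks(sid, view, lms, pixel_size):
        for name, p in lms.items():
            l_rows.append(
                {"specimen_id": sid, "view": view, "landmark_name": name,
                 "px_x": float(p[0]), "px_y": float(p[1]),
                 "pixel_size_mm": pixel_size}
            )

    for rec in records:
        sid = rec.specimen_id
        if rec.front_mask is not None:
            path = f"{sid}_front.png"
            write_mask(rec.front_mask, out / path)
            m_rows.append({"specimen_id": sid, "view": "front", "path": path,
                           "pixel_size_mm": rec.front_mask.pixel_size,
                           "plane_offset_mm": "", "phase": rec.phase or ""})
            add_landmarks(sid, "front", rec.front_landmarks, rec.front_mask.pixel_size)
        if rec.sections is not None:
            for off, m in rec.sections.planes:
                path = f"{sid}_sec{int(round(off * 1000)):05d}.png"
                write_mask(m, out / path)
                m_rows.append({"specimen_id": sid, "view": "section", "path": path,
                               "pixel_size_mm": m.pixel_size,
                               "plane_offset_mm": off, "phase": rec.phase or ""})
            add_landmarks(sid, "section", rec.section_landmarks,
                          rec.sections.masks[0].pixel_size)
    pd.DataFrame(m_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(l_rows).to_csv(out / "landmarks.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)


def read_cohort(in_dir) -> list:
    """Read a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv", keep_default_na=False)
    landmarks = pd.read_csv(src / "landmarks.csv")
    records = {}
    for row in manifest.itertuples():
        rec = records.setdefault(
            row.specimen_id, SpecimenRecord(specimen_id=row.specimen_id)
        )
        if row.phase:
            rec.phase = row.phase
        mask = read_mask(src / row.path, pixel_size=row.pixel_size_mm,
                         view=row.view, specimen_id=row.specimen_id)
        if row.view == "front":
            rec.front_mask = mask
        else:
            rec.sections = rec.sections or SectionStack(row.specimen_id, [], 0.5)
            rec.sections.planes.append((float(row.plane_offset_mm), mask))
    for rec in records.values():
        if rec.sections is not None and len(rec.sections.planes) > 1:
            rec.sections.planes.sort(key=lambda p: p[0])
            offs = [o for o, _ in rec.sections.planes]
            rec.sections.interval = float(np.round(offs[1] - offs[0], 9))
            rec.sections = SectionStack(rec.specimen_id, rec.sections.planes,
                                        rec.sections.interval)
        for view, attr in (("front", "front_landmarks"),
                           ("section", "section_landmarks")):
            sub = landmarks[(landmarks.specimen_id == rec.specimen_id)
                            & (landmarks.view == view)]
            if not sub.empty:
                setattr(rec, attr,
                        {r.landmark_name: np.array([r.px_x, r.px_y])
                         for r in sub.itertuples()})
    return [records[k] for k in sorted(records)]
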