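# Methods

## Coordinate frames and registration

All positions are expressed in cartilage-anchored millimetre coordinates.
Ventral ("front") view: the X axis lies along the upper border of the thyroid
cartilage, the Y axis along the anterior middle ridge (the neck midline), the
origin at their junction. Section view: the X axis is parallel to the cricoid
lamina through the tangent point on the anterior wall of the ring, the Z axis
the perpendicular through the same point. Orientation conventions are fixed
package-wide: +X toward the animal's left lobe, +Y cranial (so tissue below
the upper border has negative Y), +Z dorsal. These signs make the left lobe's
tabulated central point positive in X and its Y negative, matching the
reference table the pipeline reproduces.

Landmark lines are fitted by total least squares (symmetric in the
coordinates). When the fitted border and midline are not exactly
perpendicular the midline is kept exact — it is the stated neck reference —
and X is re-orthogonalized against it; frames are rejected when the two lines
subtend less than 10°, when points coincide, or when the landmark ordering
implies a mirrored image. Image pixels are mapped to a right-handed plane by
negating the row coordinate, so specimen-to-template alignment is a proper
rigid transform obtained in closed form from the two frames (origin onto
origin, axes onto axes). Scaling is off by default because photographs were
taken at a fixed shooting distance; a similarity mode keyed to the
lateral-fossa spacing (the only paired template landmark with a printed
coordinate, 0.9 mm per side) is available for uncalibrated inputs. Masks are
resampled onto the atlas grid by nearest neighbour on the inverse transform,
which preserves binarity without a threshold choice; the induced area error
is bounded by ~2 · perimeter · pixel size.

The skeleton template ships as a versioned JSON resource. Only the 0.9 mm
lateral-fossa offset and the axis incidences (upper-border points at y = 0,
midline points at x = 0, tangent point at z = 0) are normative; outline
polylines exist for plotting and are drawn to plausible adult-mouse
proportions.

## Atlas grids and rasterization

Default grids: front X ∈ [−4, 4], Y ∈ [−7, 1] mm; section X ∈ [−3, 3],
Z ∈ [−1, 3] mm; resolution 0.02 mm/px. This covers the largest observed
lobes (4 mm) with a pixel an order of magnitude finer than the 0.1 mm
precision of the printed measurements. Pixel indexing has its origin at the
grid's upper-left corner; coordinates everywhere else are continuous mm.
Polygon rasterization uses the unbiased pixel-center rule; region extents are
measured on pixel boxes (center ± half pixel), so shapes whose edges lie on
grid lines are recovered exactly.

## Volumetry and phases

Cavalieri estimate: sum of section areas × the 0.5 mm interval. Section
planning returns `floor(span/interval)` planes starting at the first complete
cartilage section (13 planes for the 6.5 mm protocol span, the printed
maximum slide count). For an ellipsoid phantom with semi-axes
(1.0, 0.3, 0.4) mm the estimate is within 1 % of 4/3·π·abc at 0.05 mm
spacing and its expected error over random lattice offsets decreases
monotonically as the interval shrinks. A Gundersen-style transitive CE
estimator is available as a diagnostic but plays no role in the defaults.

Phase bins: native below 3 mm³, then 3–6 closed, and half-open bins (6, 9],
(9, 12], (12, 15], > 15. The published one-decimal bin labels ("6.1 to 9")
leave the interval (6, 6.1) unstated; the half-open reading makes the bins an
exhaustive monotone partition of [0, ∞).

## Incidence atlas

An incidence map is the per-cell fraction k/N of registered specimen masks
covering that cell (N defaults to 6, with seeded subsampling when a phase has
more specimens). Threshold regions use an inclusive comparison so that
exactly half the cohort (3/6) belongs to the ≥ 50 % region; the "100 %"
region demands exact unanimity (≥ 1 − 1e−12), which is well defined for
integer counts. Lobes split at the canonical midline x = 0 (mouse lobes are
lateral to the trachea; the isthmus is not mapped), with exact-midline pixels
assigned by connected-component majority.

Extent conventions: front-view length is the craniocaudal (Y) box extent;
front-view **width is the widest mediolateral run within any single row** —
the lobe's width at a level. The lobes run obliquely (near the midline
proximally, lateral distally), so the full X span of a lobe exceeds its
anatomical width; the per-level definition is the one consistent with all
the printed native numbers simultaneously (length 2.0, width 0.6, medial
edge 0.5, lateral edge 1.5, central X 1.0). Section-view width is the plain
X extent (section profiles are not oblique) and thickness the Z extent.
Central points take each coordinate as the midpoint of the region's min/max
extent on that axis; Y comes from the cutting plane (default −2.0 mm, the
cricoid-ring level) when a single section plane is used — the default,
matching how the reference table was produced — with the front-region Y
midpoint as the fallback for full stacks.

## Validation metrics

Overlap rate = intersection ("blended") area over the mean of the two areas,
which is identical to the Dice coefficient; reading the blended area as the
intersection is what keeps the ratio in [0, 1]. Cohort summaries report
mean ± SEM (sample SD/√n) and the Pearson correlation of paired areas with a
two-tailed p from the t transform at n − 2 df. The published cohort values
(rate 86.2 %, r = 0.9822) are animal-dependent and serve only as
plausibility anchors, not as targets.

## Synthetic cohort generator

Each lobe is a superellipsoid (exponent 2 by default, i.e. an ellipsoid) with
semi-axes (W/2, L/2, T/2) and a mediolateral shear dx/dy = −0.2 that makes
the lobe run obliquely without changing its analytic volume, centroid, or
per-level width. A specimen's target volume is drawn from a truncated-normal
phase distribution (native 2.5 ± 0.3 on [2, 3]; enlarged phases centered in
their bins with SD 0.9; T>15 at 17.5 ± 2 on (15, 24]); lobe proportions
interpolate between the printed anchors — native 2.0 × 0.6 × 0.8 mm centered
at Y = −2.0, largest phase 4.0 × 1.6 × 1.6 mm centered 0.5 mm lower — and are
rescaled uniformly (cube root) so the two-lobe analytic volume matches the
draw exactly. The printed native dimensions alone integrate to ~1 mm³ for
ellipsoidal lobes, well short of the printed 2–3 mm³ native volume; the
generator therefore treats the printed dimensions as shape anchors and the
volume as the binding constraint, while the separate zero-noise reference
fixture cohort keeps the printed extents exactly for geometry checks.
Mediolateral lobe centers are held fixed (left 1.0, right 0.9 mm) so the
section-plane center of gravity stays put during enlargement, as observed.

Placement jitter (σ_rot = 2°, σ_trans = 0.1 mm) is applied identically to
each rendered mask and its emitted landmarks, so registration can undo it
exactly; in-vivo/ex-vivo pairs get independent residual misalignments
(σ = 0.1 mm, 1°) plus ±1 px boundary dilation/erosion. Jitter magnitudes and
noise amplitudes are invented (no published values exist) and sized to what
hand-alignment of macro photographs plausibly leaves behind. Seeding uses
`SeedSequence(master, spawn_key=(phase, index))`, making every specimen
reproducible independent of generation order.

What the generator does **not** emulate: real lobe surface texture and
histological boundaries, the isthmus, asymmetric left/right volumes,
non-rigid neck deformation, calibration error of the section photographs,
and immunization kinetics (titers, T4, the time-course growth rates). Tests
passing on synthetic cohorts therefore demonstrate correctness of the
geometry/statistics pipeline, not segmentation quality on real images —
delineation is out of scope and assumed given.

## Numerical choices and problem sizes

Atlas resolution 0.02 mm; exact-equality tests allow 2 pixels (0.04 mm).
Threshold comparisons use a 1e−12 tolerance; frame orthogonality 1e−9;
degenerate landmark angle cutoff 10°. Test and acceptance runs use compact
cohorts (≤ 6 specimens/phase, 10 for the native calibration cohort, 20
replicates per misalignment level), sizes chosen to match the study's own
per-phase N while keeping the whole suite to a few seconds. Cavalieri
convergence checks rasterize phantom sections at 0.01–0.005 mm so that
rasterization error stays an order of magnitude below the sectioning error
under test.

## Known limitations

Registration is rigid (optionally similarity) and 2-D per view; deformable
alignment and full 3-D reconstruction across sections are out of scope. The
atlas treats masks as exchangeable within a phase; no statistical shape
model or significance testing of positional differences is attempted. The
central-point Y of the reference table depends on the single chosen cutting
plane; full-stack Y midpoints are available but are not the default.
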