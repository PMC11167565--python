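"""Simulate a full synthetic cohort and map its phase-dependent topography.

Generates six seeded specimens per size phase (native through T>15), renders
their jittered photographs, section stacks and landmark sidecars, then runs
the pipeline: registration undoes the placement jitter, Cavalieri volumetry
assigns each specimen its phase, and per-phase incidence maps yield the
threshold regions.  The printed table shows how the left lobe's lateral
reach grows and its caudal tip moves down while the section-plane central
point barely moves — the topographic signature of goiter enlargement.
"""

from thyromap.cohort import CohortConfig, generate_cohort
from thyromap.pipeline import RunConfig, records_from_specimens, run_pipeline

specimens, truth = generate_cohort(CohortConfig(n_per_phase=6, seed=1))
records = records_from_specimens(specimens)
report = run_pipeline(records, RunConfig())

print("Estimated volumes by phase (mm^3):")
print(report.volumes.groupby("phase", sort=False).volume_mm3.agg(["mean", "count"]))

e = report.extents
front = e[(e.view == "front") & (e.tau == 1.0) & (e.lobe == "left")]
print("\nLeft-lobe 100% region, front view (mm): lateral reach and caudal tip")
print(front[["phase", "lateral_mm", "y_min_mm", "width_mm", "length_mm"]]
      .to_string(index=False))

print("\nSection-plane central points (mm) — nearly phase-invariant:")
print(report.central_points.to_string(index=False))

print("\nIn-vivo vs ex-vivo validation:", report.validation["summary"])
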