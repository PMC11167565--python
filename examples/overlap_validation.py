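"""Ex-vivo vs in-vivo overlap validation on synthetic pairs.

Each specimen is rendered twice with independent small misalignments and
boundary noise, emulating the residual disagreement between the thyroid
outline drawn in situ and after dissection.  The overlap rate is the blended
(intersection) area over the mean area — the Dice coefficient — and the
paired areas are compared by Pearson correlation.  Larger misalignment
lowers the mean rate; the printed summaries show the dose-response.
"""

from dataclasses import replace

from thyromap.cohort import CohortConfig, generate_specimen, render_views
from thyromap.validation import cohort_validation
from thyromap.volumetry import PHASES

base = CohortConfig(pair_rot_deg=0.5, boundary_noise_px=1)
for sigma in (0.05, 0.15, 0.3):
    cfg = replace(base, pair_trans_mm=sigma)
    pairs = []
    # one animal per size phase: the area correlation needs real size spread
    for i, phase in enumerate(PHASES):
        s = generate_specimen(cfg, phase, 100 + i)
        pairs.append(render_views(s)["pair"])
    out = cohort_validation(pairs)
    s_ = out["summary"]
    print(f"misalignment sigma {sigma:.2f} mm: rate {s_['mean_rate']:.3f} "
          f"+/- {s_['sem_rate']:.3f} (SEM), r = {s_['pearson_r']:.4f}, "
          f"p = {s_['p_two_tailed']:.2e}")
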