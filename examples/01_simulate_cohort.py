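"""Simulate a small synthetic cohort of paired pre-treatment/adaptive plans.

Each patient gets an anatomy (body, PTVs with prescriptions, nearby OARs), a
latent per-patient sparing profile, a pre-treatment dose, and a deformed
adaptive session dosed under the same sparing intent.
"""

import numpy as np

from adaptdose import PhantomConfig, generate_cohort

cfg = PhantomConfig(grid_shape=(48, 48, 32))
pairs = generate_cohort(n_patients=3, cfg=cfg, seed=7)

for pair in pairs:
    pre, ad = pair.pre, pair.adaptive
    rx = pre.ptv_map.max()
    ptv_pre = int((pre.ptv_map > 0).sum())
    ptv_ad = int((ad.ptv_map > 0).sum())
    cord = pre.oar_masks["spinal_cord"] > 0
    print(
        f"{pair.patient_id}: highest prescription {rx:5.1f} Gy | "
        f"PTV {ptv_pre} -> {ptv_ad} voxels between sessions | "
        f"cord mean dose {pre.dose[cord].mean():5.2f} Gy (pre)"
    )

# The PTV voxel count drops between sessions (tumour shrinkage) while the
# prescription stays fixed; the cord mean dose reflects that patient's
# sampled sparing strength, which an anatomy-only model cannot observe.
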