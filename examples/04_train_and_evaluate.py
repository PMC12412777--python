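"""Train a small dual-head model on a micro-cohort and evaluate it.

Desk-scale settings (tiny grid, narrow network, few epochs) so the script
finishes in a couple of minutes on one CPU; the full-scale configuration is
the library default.
"""

import numpy as np

from adaptdose import (
    NetworkConfig,
    PatchSpec,
    PhantomConfig,
    TrainingConfig,
    assemble_channels,
    build_mhunet,
    generate_cohort,
    metrics_report,
    predict_dose,
    train_model,
)

pairs = generate_cohort(5, PhantomConfig(grid_shape=(32, 32, 24)), seed=42)
train_pairs, val_pairs = pairs[:4], pairs[4:]

model = build_mhunet(NetworkConfig(base_width=4, n_levels=2, norm_groups=4, seed=0))
cfg = TrainingConfig(
    learning_rate=1e-3,
    epochs=4,
    seed=1,
    patch_spec=PatchSpec(patch_shape=(16, 16, 16), translation_sigma=(2, 2, 2)),
)
history = train_model(model, train_pairs, val_pairs, cfg)
print("validation loss per epoch:", [round(v, 5) for v in history.val_losses])
print(f"best epoch: {history.best_epoch} (val MSE {history.best_val_loss:.5f})")

pair = val_pairs[0]
pred = predict_dose(
    model,
    assemble_channels(pair.adaptive, "primary"),
    assemble_channels(pair.pre, "secondary"),
    patch_shape=(16, 16, 16),
)
report = metrics_report(
    pair.adaptive.dose, pred,
    {"spinal_cord": pair.adaptive.oar_masks["spinal_cord"]},
    highest_prescription=float(pair.adaptive.ptv_map.max()),
)
row = report.iloc[0]
print(
    f"spinal cord: ground-truth Dmean {row.gt_Dmean:.2f} Gy, "
    f"predicted {row.pred_Dmean:.2f} Gy, error {row.err_Dmean_pct:.2f}% of prescription"
)

# Losses are MSE on prescription-normalized dose; the per-structure error is
# the absolute Dmean difference as a percentage of the patient's highest
# prescription — the headline evaluation metric for dose predictors.
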