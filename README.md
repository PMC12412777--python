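# adaptdose

Dose prediction for online **adaptive radiotherapy** (ART) of head-and-neck
cancer, built around a pre-treatment-plan-conditioned dual-head 3D U-Net.

In ART a plan is re-optimized at every treatment session against that day's
anatomy. Population dose predictors speed this up, but they usually see only
the session's contours and CT — they are blind to the per-patient trade-offs
the physician already encoded in the approved *pre-treatment* plan. This
package implements, end to end:

* a **dual-head 3D encoder–decoder**: the primary head encodes the adaptive
  session (44 organ-at-risk masks + 44 distance maps + PTV prescription map
  + CT = 90 channels); a secondary head encodes the pre-treatment session
  plus its approved dose (91 channels). Downsampling concatenates 2x2x2 max
  and average pooling; upsampling concatenates nearest-neighbour, trilinear,
  and transposed-convolution branches; the pooled secondary features are
  fused into the primary stream at each level and the streams merge in a
  512-channel bottleneck. A single-head U-Net baseline shares every block;
* the **preprocessing** that builds those channel stacks (PTV merging by
  highest prescription, per-structure distance maps `exp(-d/tau)`, fixed
  44-structure roster with zero-filled absent channels);
* the **training protocol**: Adam, MSE on prescription-normalized dose,
  batch size 1, PTV-centred random patches with flip/right-angle rotation
  augmentation, best-validation checkpointing;
* a **dosimetric evaluation suite**: cumulative DVHs, D99/D98/D95/D50/D2,
  Dmean/Dmax, homogeneity index `(D2−D98)/D50`, absolute percent error
  normalized by the highest prescription, and paired two-tailed Wilcoxon
  signed-rank comparison of two models;
* a **synthetic phantom cohort generator** producing paired
  pre-treatment/adaptive sessions with a latent per-patient organ-sparing
  profile that is observable *only* through the pre-treatment dose — the
  statistical structure the dual-head model exists to exploit (the clinical
  cohort is private).

Everything runs on a small numpy reverse-mode autodiff engine included in
the package (`adaptdose.nn`); no deep-learning framework is required.

## Worked example

```python
import numpy as np
from adaptdose import (
    NetworkConfig, PatchSpec, PhantomConfig, TrainingConfig,
    assemble_channels, build_mhunet, generate_cohort,
    metrics_report, predict_dose, train_model,
)

pairs = generate_cohort(5, PhantomConfig(grid_shape=(32, 32, 24)), seed=42)
model = build_mhunet(NetworkConfig(base_width=4, n_levels=2, norm_groups=4, seed=0))
history = train_model(
    model, pairs[:4], pairs[4:],
    TrainingConfig(learning_rate=1e-3, epochs=4, seed=1,
                   patch_spec=PatchSpec(patch_shape=(16, 16, 16),
                                        translation_sigma=(2, 2, 2))),
)
print("validation loss per epoch:", [round(v, 5) for v in history.val_losses])

pair = pairs[4]
pred = predict_dose(model,
                    assemble_channels(pair.adaptive, "primary"),
                    assemble_channels(pair.pre, "secondary"),
                    patch_shape=(16, 16, 16))
report = metrics_report(pair.adaptive.dose, pred,
                        {"spinal_cord": pair.adaptive.oar_masks["spinal_cord"]},
                        highest_prescription=float(pair.adaptive.ptv_map.max()))
row = report.iloc[0]
print(f"spinal cord: ground-truth Dmean {row.gt_Dmean:.2f} Gy, "
      f"predicted {row.pred_Dmean:.2f} Gy, error {row.err_Dmean_pct:.2f}%")
```

This prints (see `examples/04_train_and_evaluate.py`):

```
validation loss per epoch: [0.01193, 0.00605, 0.00568, 0.00551]
best epoch: 3 (val MSE 0.00551)
spinal cord: ground-truth Dmean 6.93 Gy, predicted 0.93 Gy, error 11.42% of prescription
```

The loss is MSE on dose normalized by the 72 Gy cohort maximum prescription;
the report row says the spinal cord's mean dose was predicted within 11.4% of
this patient's highest prescription — the standard headline metric for dose
predictors. A four-epoch toy run at width 4 is illustrative only;
`docs/methods.md` describes the desk-scale study configuration used by the
acceptance suite.

The same pipeline is scriptable from the shell:

```bash
adaptdose simulate --n 28 --seed 7 --out cohort/
adaptdose train --model mhunet --cohort cohort/ --n-val 4 --out run/
adaptdose predict --checkpoint run/best.npz --cohort cohort/ --out pred/
adaptdose evaluate --cohort cohort/ --pred pred/ --out eval/
adaptdose model summarize --kind mhunet        # per-level shape audit
```

## Layout

```
src/adaptdose/       library (volume I/O, preprocessing, nn engine,
                     networks, training, dosimetry, phantom, CLI)
examples/            one short narrative script per capability
docs/methods.md      models, conventions, generator design, limitations
tests/               pytest suite incl. the acceptance checks
scripts/acceptance.py
```
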