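# sonomil

Two-stage deep learning for predicting **axillary lymph node (ALN)
metastasis** in breast cancer from a patient's multi-view ultrasound
examination, together with a synthetic speckle-phantom cohort generator
and the full diagnostic-accuracy evaluation stack (DeLong tests,
decision-curve analysis, PR curves, mIoU, chi-square cohort
comparisons, a clinical logistic baseline).

ALN status drives surgical planning in early breast cancer, and
preoperative ultrasound shows both the primary tumor and — when visible
— the axillary nodes. `sonomil` mirrors that diagnostic workflow in two
stages:

1. **Image-level multi-task network.** Each view (tumor or node) passes
   a shared backbone and a light mask decoder that segments the lesion
   (`ŷ_seg`), classifies the lesion type, and predicts image-level
   metastasis. The predicted segmentation acts as a soft attention
   gate — `z_m = s ⊙ pool(ŷ_seg)`, `z_c = z ⊙ pool(ŷ_seg)` — so the
   classifiers only see evidence inside the predicted lesion, which
   suppresses background shortcuts and makes the class activation maps
   (CAM, exact for the pool-then-linear heads) concentrate on lesions.
2. **Patient-level multi-instance learning.** The gated features of all
   of a patient's views become 256-d tokens; a CLS-token transformer
   (permutation-invariant, padding-masked, no positional embeddings)
   pools the variable-size bag — including bags with no node views —
   into a single patient probability, trained with binary cross-entropy.

Clinical images are private, so the package ships a seeded phantom
generator that plants the relevant sonographic signs (hypoechoic
lesions on multiplicative speckle, loss of the bright fatty hilum,
rounder and more irregular metastatic nodes, a weak tumor-side signal)
with fully known ground truth. See `docs/methods.md` for the model,
generator, and every numerical convention.

The networks run on a small self-contained numpy autodiff engine
(`sonomil.autograd`) — no GPU framework is required.

## Worked example

```python
import tempfile
from sonomil.phantom import CohortSpec, simulate_cohort, write_cohort
from sonomil.training import (TrainConfig, train_mtl, train_mil,
                              predict_patients)
from sonomil.metrics import auc_ci, confusion_at

root = tempfile.mkdtemp()
spec = CohortSpec(n_patients=400, seed=0)           # 64.2% ALN-positive
manifest = write_cohort(simulate_cohort(spec), root, train_ratio=0.75)

mtl_cfg = TrainConfig.desk("mtl", seed=0)           # 96x96, tiny backbone
net, log = train_mtl(mtl_cfg, manifest, root)

mil_cfg = TrainConfig.desk("mil", seed=0)
(extractor, bag_model), _ = train_mil(mil_cfg, manifest, root,
                                      mtl_net=net, mtl_config=mtl_cfg)

preds = predict_patients(manifest, root, net, mtl_cfg,
                         extractor, bag_model, split="internal_test")
auc, lo, hi = auc_ci(preds["probability"], preds["label"])
c = confusion_at(preds["probability"], preds["label"], 0.5)
print(f"held-out AUC {auc:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"sensitivity {c.sensitivity:.3f}  specificity {c.specificity:.3f}")
```

On the 100 held-out phantom patients this prints

```
held-out AUC 0.890 (95% CI 0.817-0.964)
sensitivity 0.710  specificity 0.871
```

— the model recovers the planted node-dominant metastasis signal from
the bags (exact numbers vary a little with the seed). A
tumor-views-only ablation trained identically lands clearly lower
(≈ 0.68-0.76),
mirroring the clinical finding that single-view tumor models
underperform joint tumor+node prediction; with all planted effects
switched off the held-out AUC collapses to chance.

The same pipeline is available from the shell:

```sh
sonomil simulate --config cohort.json --out cohort/ --seed 0
sonomil train-mtl --manifest cohort/manifest.csv --root cohort/ --out run/mtl
sonomil train-mil --manifest cohort/manifest.csv --root cohort/ \
        --mtl-checkpoint run/mtl/mtl.npz --out run/mil
sonomil predict  --manifest cohort/manifest.csv --root cohort/ \
        --mtl-checkpoint run/mtl/mtl.npz --mil-checkpoint run/mil/mil.npz \
        --out preds.csv
sonomil evaluate --scores preds.csv --out report/
sonomil cam --image cohort/images/P00001_node_1.png \
        --mtl-checkpoint run/mtl/mtl.npz --out cam.png
```

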