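# wheatvision

Online detection of the **impurity rate** of mechanically harvested wheat
from camera images of the grain stream.

When a combine harvester threshes wheat, the tank holds grain mixed with
straw, awn and husk fragments. The impurity rate — the mass percentage of
that non-grain material — is a headline quality indicator, but measuring it
traditionally means stopping the machine, sampling ~500 g, separating the
components by hand and weighing them. `wheatvision` implements the
vision-based alternative: semantically segment each camera frame into
background / grain / impurity pixels with a DeepLabV3+ encoder–decoder,
then convert pixel counts into a mass-based rate through a calibrated
constant.

## The model

**Segmentation.** A DeepLabV3+ network with selectable backbones
(`mobilenetv2`, `resnet50`, `resnet101`, `xception65`, plus a width-scalable
`tiny` backbone for desk-scale work). The encoder replaces the last stage's
stride with atrous (dilated) convolution and applies atrous spatial pyramid
pooling (ASPP) — parallel 3×3 branches at dilation rates (6, 12, 18), a 1×1
branch and a global-pooling branch, fused by a 1×1 projection. The decoder
upsamples ×4, concatenates a low-level backbone feature, refines, and
upsamples to full resolution, giving per-pixel scores for 3 classes.
The network runs on a small numpy autodiff engine (`wheatvision.nn`), so no
deep-learning framework is required.

**Quantification.** With `T_w` grain pixels and `T_z` impurity pixels in a
predicted mask,

    P_z  = T_z / (T_z + ∂·T_w) × 100          (device impurity rate, %)
    P_cz = w_z / w × 100                       (manual mass-based rate, %)

where ∂ is the ratio of grain mass to impurity mass carried per 1000
pixels. The laboratory-calibrated default is ∂ = 11.8906;
`calibrate_delta` re-estimates it from weighed, pixel-counted samples.

**Evaluation.** Per class: precision P, recall R, F1 = 2PR/(P+R),
F_IOU = TP/(TP+FP+FN); F_MIOU averages the grain and impurity IOUs.
Device-vs-manual trials are summarised by the absolute error
R_az = |P̄_Sz − P̄_Mz|, the relative error R_rz = R_az/P̄_Mz × 100, and the
coefficients of variation of both series.

Because no public image set exists, the package ships a synthetic scene
generator (`wheatvision.synthetic`): grain piles rendered as ellipse blobs
with straw strips and husk arcs, with exact ground-truth masks, LabelMe
JSON polygons and known per-1000-pixel masses, so the full chain is
testable end to end.

## Worked example

```bash
wheatvision simulate --out raw --n-images 20 --seed 1
wheatvision prepare  --data raw --out prepared --size 512 --counts 14,2,4 --seed 1
wheatvision train    --data prepared --out model.npz --backbone tiny \
                     --width-multiplier 0.5 --epochs 5 --seed 0
wheatvision evaluate --checkpoint model.npz --data prepared --out metrics.csv
wheatvision calibrate --samples raw/manifest.csv --out calib.json
wheatvision detect   --checkpoint model.npz --images raw --calibration calib.json \
                     --out detections.csv
```

The same pipeline run by `scripts/acceptance.py --seed 1` on 200 synthetic
128×128 scenes prints:

```
   class     P     R    F1  F_IOU F_MIOU
   grain 95.84 94.57 95.20 0.9084 0.7434
impurity 78.89 68.44 73.30 0.5785 0.7434
calibrated delta = 12.0392 (true 11.8906, n=30)
    label  P_Sz_mean  P_Mz_mean     R_Scv     R_Mcv     R_az      R_rz
synthetic   0.605408   0.882395 36.745048 14.892808 0.276987 31.390332
```

Reading it: the desk-scale network reaches a two-class mean IOU of 0.74 on
held-out scenes (grain is easier than thin straw, as in real imagery);
calibration recovers the true mass ratio within ~1% from 30 weighed samples
at 5% weighing noise; and the device-vs-manual comparison mirrors a bench
trial — the device mean sits below the manual mean here because residual
under-segmentation of thin straw propagates directly into the pixel rate.

As a library:

```python
import wheatvision as wv

scene = wv.render_scene(wv.SceneSpec(seed=7))
rate = wv.pixel_rate(scene.true_counts)        # uses the default ∂ = 11.8906
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the whole pipeline from scratch — synthetic dataset, DeepLabV3+
training, held-out metric evaluation, ∂ calibration under weighing noise,
and the trial error statistics — and writes its JSON result object. All
randomness derives from `--seed`.
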