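# peelnet

Image-based authentication of dried citrus peel (*Citri Reticulatae
Pericarpium*, CRP) vintage from consumer-camera photographs.  The market
value of CRP rises steeply with aging, and lower-grade peel is routinely
dressed up as premium product; `peelnet` targets the resulting
classification problem — assign a peel photograph to one of four
price-tier classes (190 / 560 / 2800 / 3300 CNY per kg) — without
laboratory instrumentation.

The method has three stages:

1. **Region localization.**  A detector proposes boxes around the whole
   specimen, the outer surface (exocarp) and the inner pith (albedo); each
   box is tightened by grayscale corner-deviation refinement: with global
   mean gray `μ` and threshold `τ`, any corner whose deviation
   `Δ = |I(x, y) − μ|` exceeds `τ` pulls its coordinates inward by step
   `s`, until all corners are within `τ`.  The threshold derives from the
   scene: `τ = |μ_specimen − μ_background| / 2`, giving the operating value
   `τ = 20` for the rig's ≈40-level gray gap.
2. **Three-branch classification.**  Whole image, exocarp patch and albedo
   patch each feed a four-stage residual backbone.  After stage 2 the
   branches exchange channels: a random 10% of whole-branch channels
   overwrite the same channels of each local branch, then independent 5%
   sets flow back.  Stage-4 maps are compressed 2048→512 by 1×1
   convolutions, pooled, concatenated into a 1536-d fused vector and
   classified by a softmax head with per-branch auxiliary losses.
3. **Cross-device meta-learning.**  Each camera is a domain.  MAML
   meta-training on the source device (inner loop: K=5 gradient steps on a
   4-way 5-shot support set; outer loop: aggregated query losses,
   second-order meta-gradients) yields an initialization that adapts to a
   new device from five labeled images per class.

Real specimen photographs are not redistributable, so the package includes
a synthetic specimen generator (elliptical peel on a uniform backdrop,
calibrated 40-level gray gap, four appearance classes with fine-grained
pith cues, three device-style photometric domains with paired specimens).
Every experiment below runs from a seed with no external data.  The
classifier and meta-learner run on a small functional numpy engine with
hand-written backprop (`peelnet.nn`); gradients are verified against
finite differences in the test suite.

## Worked example

Generate a small dataset, localize and refine regions, and inspect one
refinement:

```bash
peelnet generate --out data --seed 7 --n-per-class 10
# wrote 120 manifest rows to data/manifest.csv

peelnet localize --manifest data/manifest.csv --out boxes.csv
# wrote 360 boxes to boxes.csv

peelnet refine --image data/cam0/spec0000_c190.png --box 0,0,159,159 --tau 20
# {"box": [32, 31, 129, 128], "iterations": 16, "converged": true}
```

The box shrank from the full 160×160 frame into the specimen: each
iteration moved every corner whose gray value deviated from the image mean
by more than τ=20 (background corners, deviating by gap·fill-fraction
≈ 23), and stopped once all corners lay on peel surface (deviation ≈ 13).
Corners travel diagonally, so the final box is inscribed in the elliptical
specimen rather than circumscribing it.

Train the three-branch classifier on a synthetic set (24 specimens per
class by default) and evaluate:

```bash
peelnet run --run-dir runs/demo
```

writes `runs/demo/metrics.json` with the held-out test report — here
`"accuracy": 0.95`, macro F1 0.949, and a 4×4 confusion matrix whose rows
sum to the per-class test counts — plus `boxes.csv` (360 refined boxes,
every refinement converged) and a copy of the config and seed for
reproduction.

From the library, the cross-device benchmark:

```python
from peelnet.experiments import device_shift_benchmark
res = device_shift_benchmark(seed=0)
print(res.direct["cam2"]["accuracy"], res.adapted["cam2"].mean_accuracy)
```

prints the direct-transfer accuracy of the source-trained model on the
shifted device and the mean accuracy after 5-shot adaptation (10 support
draws); adaptation recovers a large part of the drop caused by the
device's color-matrix/blur/noise shift.

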