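# ctlungseg — pediatric chest CT lung segmentation

Automatic lung segmentation in chest CT of preschool children. Adult
lung segmenters fail on this population for three reasons: the thorax
occupies less than 20 % of the 512×512 frame, patient motion produces
streak artifacts, and failed breath-holds collapse localized lung
regions toward soft-tissue density. `ctlungseg` addresses all three
with a three-stage pipeline:

1. **Crop-and-zoom preprocessing** — Gaussian denoising
   (σ = 3 px), HU thresholding + morphological opening + largest
   connected domain to locate the body, crop to its circumscribed
   rectangle, zoom to 256×256 (invertibly, so results are reported in
   original coordinates).
2. **A concatenative ResUnet** — a U-shaped encoder–decoder whose
   blocks concatenate their input features with their convolved
   features, with Leaky-ReLU activations and dropout, trained with the
   compound objective

   L_all = α·log(L_Dice) + L_f, α = 0.3,

   where L_Dice = 1 − 2|e∩f|/(|e|+|f|) and L_f is the focal loss;
   optimization is RMSprop (lr 0.001, 10 epochs).
3. **A case-based 3D filter** — the slicewise predictions of a case
   are stacked, labeled in 3D, and only the two largest centrally
   located volumes (the left and right lungs) are kept, removing
   missegmentations such as table edges and pre-scan frames.

Because clinical pediatric CT with gold-standard masks is not freely
distributable, the package includes a **synthetic phantom generator**
reproducing the three pediatric challenges (small chest fraction,
streaks, breath-hold dropout) with exact ground truth and defect logs;
the whole pipeline trains and evaluates end-to-end on phantoms. The
network and its training loop run on a small NumPy reverse-mode
autodiff engine included in the package (`ctlungseg.nn`) — no GPU or
deep-learning framework required.

Intended users: researchers in medical image analysis who need a
tested, dependency-light reference implementation of this pipeline, or
a controllable phantom benchmark for segmentation post-processing.

## Worked example

```python
from ctlungseg import LungSegmenter, ModelConfig, TrainConfig, PreprocessConfig

model = LungSegmenter.from_phantoms(
    n_cases=32, n_slices=10, seed=1, slice_size=192,
    model_config=ModelConfig(base_channels=8, depth=3),
    train_config=TrainConfig(seed=1, test_cases=12),
    preprocess_config=PreprocessConfig(out_size=128),
)
results = model.fit()          # preprocess → split → train → segment → score
print(results.summary())
```

On one CPU this trains the reduced network on 200 phantom slices
(~4 minutes) and prints, for the 12 held-out cases:

```
          Pediatric CT Lung Segmentation Results
================================================================
Architecture:     ResUnet (res blocks, depth 3, base 8)
Parameters:       142,618
Loss:             combined (alpha=0.3)
Optimizer:        rmsprop (lr=0.001, epochs=10, batch=8)
Training slices:  180  (validation 20)
Held-out cases:   12  (failed: 0)
Best epoch:       8
----------------------------------------------------------------
Held-out case scores
              IOU   Dice  Precision  Recall
case
phantom-2  0.9820 0.9909     0.9917  0.9901
phantom-4  0.9859 0.9929     0.9926  0.9932
...
Average    0.9841 0.9920     0.9916  0.9924
================================================================
```

Each row scores one held-out case in original coordinates (IOU, Dice,
precision, recall of predicted vs ground-truth lung voxels); the
Average row is the unweighted mean over cases. `results.predict(ct)`
segments a new `CTVolume` end-to-end, and
`results.save("model.npz")` stores the fitted weights with the
architecture config embedded.

A command-line interface mirrors the pipeline stages:

```bash
ctlungseg synth --n-cases 4 --n-slices 10 --seed 1 --out raw/
ctlungseg preprocess --in raw/ --out pre/ --sigma 3 --out-size 256
ctlungseg train --in pre/ --model-out model.npz
ctlungseg predict --model model.npz --in raw/ --out pred/
ctlungseg evaluate --pred-dir pred/ --gt-dir raw/ --report report.csv
ctlungseg run-all --out results/        # all stages in one go
```

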