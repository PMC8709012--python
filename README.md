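# fundusnet

Deep-feature extraction and multilevel feature selection for ophthalmic
image classification, built around three components:

1. **A residual CNN+LSTM feature extractor.** A convolutional stem feeds a
   stack of residual blocks (conv→BN→ReLU→conv→BN with a skip connection,
   ReLU after the add); the final feature map is unfolded row-wise into a
   sequence read by an LSTM, whose last hidden state drives a fully
   connected layer. The activations of that first fully connected layer
   (FC1, width 350 by default) are the *deep features* handed to a separate
   classifier. Ablation variants (`cnn`, `cnn_lstm`, `rcnn`, `rcnn_lstm`)
   drop the skip connections and/or replace the LSTM with flattening. The
   network, including all backward passes and the SGD-with-momentum
   trainer, is implemented in numpy (`fundusnet.nn`).

2. **NCAR, a two-level feature selector.** Level 1 fits neighbourhood
   component analysis (NCA) weights by maximising the regularised expected
   leave-one-out neighbour accuracy

   F(w) = (1/n) Σᵢ Pᵢ − λ Σᵣ wᵣ²,   Pᵢ = Σ_{j : yⱼ=yᵢ} p_ij,
   p_ij ∝ exp(−d_w(xᵢ,xⱼ)/σ),   d_w(xᵢ,xⱼ) = Σᵣ wᵣ² |x_ir − x_jr|,

   and drops features with weight < 0.0005. Level 2 recomputes ReliefF
   importance weights

   W(a) ← W(a) − Σⱼ diff(a,Rᵢ,Hⱼ)/(mk) + Σ_{C≠class(Rᵢ)} [P(C)/(1−P(class(Rᵢ)))] Σⱼ diff(a,Rᵢ,Mⱼ)/(mk)

   on the survivors (k = 10 nearest hits/misses, range-normalised `diff`)
   and drops those below 0.01.

3. **An evaluation harness.** Stratified 10-fold cross-validation over
   DT / LD / NB / SVM / KNN classifiers with in-fold z-scoring, pooled
   confusion matrices, per-class one-vs-rest sensitivity / specificity /
   precision / F-score, macro averages, and one-vs-rest ROC AUC.

Because the clinical dataset this design targets is not redistributable,
the package ships a synthetic-data module: labelled Gaussian feature tables
with a known informative subset, and eight-class retinal *phantoms*
(fundus-like images with class-specific structures — drusen for AMD, haze
for cataract, exudates for diabetic retinopathy, an enlarged disc for
glaucoma, tortuous vessels for hypertension, a peripapillary crescent for
pathological myopia). Every stage is testable end to end with known ground
truth.

## Worked example

```python
import numpy as np
from fundusnet import (
    SynthImageSpec, generate_phantom_images,
    ModelConfig, TrainConfig, build_model, train_model, extract_deep_features,
    NCAConfig, ReliefFConfig, ncar_select, ClassifierSpec, stratified_cv,
)

images, labels = generate_phantom_images(
    SynthImageSpec(n_per_class=40, image_size=32, seed=0))

config = ModelConfig(n_residual_blocks=2, block_filters=(12, 16),
                     lstm_units=16, fc1_width=350, n_classes=8, input_size=32)
model = build_model(config, seed=0)
model, history = train_model(model, images, labels,
                             TrainConfig(batch_size=32, learning_rate=0.01,
                                         max_epochs=40, seed=0))
print(f"training accuracy {history.accuracy[-1]:.3f}")

features = extract_deep_features(model, images).matrix          # (320, 350)
selection = ncar_select(features, labels,
                        NCAConfig(solver="lbfgs", max_iters=1000, seed=0),
                        ReliefFConfig(seed=0))
print(f"NCAR kept {selection.n_selected}/350 features")

report = stratified_cv(features[:, selection.keep_mask], labels,
                       ClassifierSpec("SVM"), k=10, seed=0)
print(f"SVM 10-fold accuracy {report.accuracy:.3f}")
```

Output:

```
training accuracy 1.000
NCAR kept 29/350 features
SVM 10-fold accuracy 1.000
```

The extractor learns the eight phantom classes; NCAR discards over 90% of
the 350 deep features (the FC1 layer spans only a 16-dimensional recurrent
state here, so most columns are redundant), and the SVM classifies the
selected 8% perfectly under cross-validation — the selector shrinks the
classifier's input without costing accuracy.

The same pipeline is available from the shell:

```bash
fundusnet run-all --out-dir run --n-per-class 20 --max-epochs 30 --seed 0
fundusnet synth-gen --kind table --out table.csv --seed 0
fundusnet select table.csv --out-prefix selection
fundusnet evaluate table.csv --classifier SVM --out metrics.json
```

Short narrative scripts, one per capability, live in `examples/`.

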