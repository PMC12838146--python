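# radfuse

Radiomics-guided multimodal classification of 2-D medical-style images.

Many lesion-classification problems carry their signal in two complementary
places: handcrafted radiomic descriptors (first-order intensity statistics,
2-D shape, GLCM/GLRLM texture) capture local tissue character inside a region
of interest, while a trainable convolutional encoder captures global context
that no within-ROI statistic sees.  `radfuse` fuses the two branches and
actively manages their redundancy:

* **Anti-cross-attention (ACA) fusion.**  With row-normalized branch features
  `Rp = Norm(Wrp R + brp)` and `Fn = Norm(F)`, each sample's bilinear
  interaction matrix `M_b = (r_p W)^T f_n` is batch-normalized and softmaxed
  along the deep-feature axis into an attention map `A`.  The block then uses
  the *inverse* map `A_inv = 1 - A`: the column sums (divided by `d`) form a
  weight vector that **up-weights the deep channels receiving low standard
  attention** — the weakly correlated, complementary dimensions.  A learnable
  sigmoid gate `g` blends this with a residual pass-through,
  `Fatt = Fn ⊙ (g·a + (1-g))`, and the fused vector is
  `Ffus = BN(Concat(Rp, Fatt))`.
* **Cross-covariance decorrelation loss.**  Two MLP-projected latent views
  `H1, H2` of the branches are centered and the loss
  `L_dec = ||C12||_F² = Σ_ij (H1'^T H2' / (B-1))²_ij` penalizes linear
  dependence between them.  Its weight ramps linearly,
  `α = α_max · epoch / n_epochs` (default `α_max = 0.2`), so classification
  dominates early training: `L_tot = L_ce + α·L_dec`.
* **Spline (Kolmogorov–Arnold) head.**  The classifier places learnable
  univariate functions on edges: a B-spline expansion (grid size 5, order 3,
  Cox–de Boor recursion) plus a smooth base term per edge.  A plain
  fully-connected head is available as a drop-in alternative.
* **Radiomics branch.**  IBSI-style extraction (48 features: first-order,
  shape, GLCM at distances 1–3, GLRLM), z-scored on the training split, then
  reduced by cross-validated L1-penalized multinomial selection.

A synthetic lesion-image generator with independently tunable texture, shape
and context effects — and a one-knob cross-modal `redundancy` parameter —
makes every stage testable end to end without any external data.

## Worked example

```python
import numpy as np
from radfuse import (SynthConfig, generate_dataset, stratified_split,
                     FusionImageClassifier, evaluate)

cfg = SynthConfig(n_classes=3, n_per_class=60, image_size=64,
                  texture_effect=2.0, shape_effect=2.0, context_effect=2.0,
                  redundancy=0.3, seed=0)
samples, manifest = generate_dataset(cfg)
X = np.stack([s.image for s in samples])
M = np.stack([s.mask for s in samples])
y = manifest["label"].to_numpy()

tr, te = stratified_split(y, ratio=0.8, seed=0)
clf = FusionImageClassifier(epochs=15, unified_dim=32, native_dim=64,
                            learning_rate=1e-3, random_state=0)
clf.fit(X[tr], y[tr], masks=M[tr])
report = evaluate(clf, X[te], y[te], masks=M[te])
print(f"acc={report.acc:.3f} auc={report.auc:.3f} "
      f"sen={report.sen:.3f} spe={report.spe:.3f}")
print(clf.selected_names_[:5])
```

prints

```
acc=0.861 auc=0.969 sen=0.861 spe=0.931
['shape_area', 'glcm_d1_correlation', 'shape_circularity', 'glcm_d2_homogeneity', 'shape_perimeter']
```

i.e. on strongly separated synthetic classes the fused model reaches 86%
test accuracy (macro AUC 0.97), and the embedded selection surfaces exactly
the feature families the generator manipulates (shape area / circularity /
perimeter for the ellipse channel, co-occurrence correlation / homogeneity
for the texture channel).  `clf.history_` holds the
per-epoch `L_ce`, `L_dec`, `alpha` and validation metrics.

The same pipeline is scriptable from the shell:

```bash
radfuse simulate --config sim.yaml --out data/
radfuse extract-features --manifest data/manifest.csv --out features.csv
radfuse train --config train.yaml
radfuse ablate --config train.yaml    # baseline / +ACA / +deco / +KAN ladder
```

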