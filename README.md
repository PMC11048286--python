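# cst — convolutional sparse transformer for raw-waveform EEG

`cst` is a toolkit for classifying multichannel EEG directly from the raw
waveform — seizure monitoring, psychiatric diagnosis (e.g. major depressive
disorder), pharmaco-EEG drug classification, and treatment-response
prediction all reduce to the same problem: assign a class label to a
fixed-length epoch **X ∈ ℝ^{T×C}** (T time frames × C electrode channels)
without hand-crafted features.

## The model

The classifier is an encoder stack with three ideas layered on a vanilla
transformer:

1. **Spatial channel attention.** Electrode channels carry very unequal
   information (a temporal-lobe seizure lives on a few electrodes).  A
   per-channel gate
   `M_c(X) = σ(W₁W₀ X_avg + W₁W₀ X_max) ∈ (0,1)^C`
   is computed from time-pooled channel statistics by a shared
   squeeze-and-excite MLP and multiplied into the raw signal.

2. **Equidistant sparse self-attention.** Dense self-attention costs
   O(L_Q·L_K) over sequence length L.  Here only
   `u = ⌈c·ln L⌉` *active* query positions, placed at equidistant intervals
   `idx_k = ⌊kL/u⌋`, attend over the full key set:
   `A(q_i,K,V) = Σ_j k(q_i,k_j)/Σ_l k(q_i,k_l) · v_j`,
   `k(q_i,k_j) = exp(q_i k_jᵀ/√d)`.
   Every other ("lazy") position is filled with the exact column mean of V.
   The cost falls to O(L_K·ln L_Q) — at L = 1024 only 7/1024 of the dense
   query-key dot products are computed.

3. **Distilling convolutional layers.** After an encoder layer, a
   `X_{j+1} = MaxPool(ELU(Conv1d(X_j)))`
   stage fuses temporally adjacent features and halves the sequence length,
   so an 8 s epoch at 256 Hz (T = 2048) leaves a 5-stage stack at length 64.

The default configuration is 3 sparse + 3 full attention layers, 8 heads,
d_model 128, d_ff 512, 5 convolution + 5 pooling layers; a mean-pool +
affine head emits class logits.  The whole network — forward *and*
backward — runs on a small NumPy reverse-mode autodiff engine
(`cst.autodiff`), so the package has no deep-learning framework dependency.

Around the model the package provides EDF/CSV readers, zero-phase
Butterworth filtering, epoch segmentation with annotation-overlap
labelling, stratified/grouped splits, a full metric suite (accuracy,
precision, recall, F1, ROC-AUC, confusion matrices), repeated-holdout and
k-fold protocols, an ablation switchboard and a hyperparameter sensitivity
sweep — plus a synthetic EEG generator (1/f^β background + band-limited
class oscillations + ictal-like bursts) so everything is testable without
clinical data.

## Worked example

Train the reduced desk-scale encoder on the built-in synthetic benchmark
(two classes on 4-channel, 128 Hz, 4 s epochs; the "alpha" class carries a
strong 8–13 Hz oscillation on channels 0–1):

```python
from cst import (ConvSparseTransformer, ModelConfig, TrainConfig,
                 make_dataset, two_class_alpha_task, split_holdout)

task = make_dataset(two_class_alpha_task(n_per_class=100))
train, test = split_holdout(task, 0.7, seed=0)
config = ModelConfig(in_channels=4, n_classes=2,
                     n_sparse_layers=2, n_full_layers=1,
                     n_conv_layers=3, n_pool_layers=3,
                     d_model=64, d_ff=128, n_heads=8, seed=0)
res = ConvSparseTransformer(train, config).fit(
    TrainConfig(epochs=3, batch_size=32, seed=0))
print(res.summary())
print(res.evaluate(test).summary())
```

which prints

```
Convolutional Sparse Transformer — fit summary
====================================================
epochs (data)        : 140
epoch shape [T x C]  : 512 x 4
classes              : ['background', 'alpha']
attention layers     : 2 sparse + 1 full (8 heads)
d_model / d_ff       : 64 / 128
distilling layers    : 3
channel attention    : True
sparse attention     : True (query factor 1.0)
parameters           : 138450
training             : 3 epochs, batch 32, lr 0.001
loss first -> last   : 0.6070 -> 0.0371

metric      value
accuracy    1.0000
precision   1.0000
recall      1.0000
f1          1.0000
roc_auc     1.0000

confusion matrix (rows = true class):
background       30      0
alpha             0     30
```

The cross-entropy falls from 0.61 (chance is ln 2 ≈ 0.69) to 0.04 in three
passes, and the held-out 60 epochs are classified perfectly — the band-power
difference between the two synthetic classes is deliberately easy; the point
of the example is that the full pipeline (gating → embedding → sparse
attention → distillation → prediction) is wired correctly.

There is also a CLI over the same machinery:

```bash
cst simulate --config run.yaml --out data/
cst train    --config run.yaml --out run/
cst eval     --config run.yaml --checkpoint run/checkpoint.npz --out run/
cst ablate   --config run.yaml --out run/
cst sweep    --config run.yaml --out run/
```

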