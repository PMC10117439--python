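# szgcn

Multimodal brain-graph construction and graph-convolutional-network
classification for two-group (patient vs. control) MRI cohorts, with
node-saliency explainability and a seeded synthetic phantom generator.

## What it does

Discriminative connectomics studies of schizophrenia represent each
subject as a **brain graph**: nodes are atlas regions (ROIs, e.g. 90 or
246 per atlas), node features are regional structural/functional
measures, and edges are inter-regional connectivity.  This package
implements that pipeline end to end:

1. **Node features** — per ROI: mean gray-/white-matter value (GMV,
   WMV), amplitude of low-frequency fluctuation (ALFF, mean √power over
   0.01–0.08 Hz, globally normalised), regional homogeneity (ReHo,
   Kendall's W over a voxel's 26-connected neighbours, globally
   normalised), and structural/functional degree centrality (row sums
   of the weighted connectivity matrices).
2. **Edge features** — three N×N constructions per subject: the gray
   matter matrix **GMM** (morphological similarity,
   `exp(−sym-KL)` between ROI gray-matter value densities), the
   functional brain matrix **FBM** (|Pearson r| between ROI mean time
   series), and **GMM-FBM** (both min-max normalised and summed).
   Binary graphs retain exactly the top fraction *p* of edge weights
   ("proportional quantification"); the Erdős–Rényi floor `2 ln N / N`
   motivates default sparsities of 10% (N=90) and 5% (N=246).
3. **Classifier** — three blocks of graph convolution
   `H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` → TopK pooling
   (`y = Hp/‖p‖`, keep `k = ⌈0.8N⌉` nodes, gate by `tanh y`) → readout
   (max ‖ mean); summed readouts feed a fully connected head.  Trained
   with Adam (lr 1e-4), batch 30, dropout 0.5, cross-entropy and early
   stopping — implemented entirely in NumPy with hand-derived,
   finite-difference-verified gradients.
4. **Saliency** — per training subject the 20 top-scored survivors of
   the last pooling layer are counted; a region's significance score is
   its selection frequency over 20 × n_train.
5. **Evaluation** — stratified repeated random splits (300:45
   proportion), six metrics (accuracy, AUC, sensitivity, specificity,
   F1, precision), a 5–50% sparsity sweep, and the demographic-table
   statistics (Yates χ², Welch t).

Because cohorts of this kind are private, the package validates itself
on **synthetic phantoms**: a seeded generator plants gray-matter volume
decrements and functional-coupling reductions in a known ROI subset,
and the pipeline must recover them.  See `docs/methods.md` for the full
model description and design decisions.

## Worked example

```python
import szgcn

atlas = szgcn.make_atlas_phantom(90)
config = szgcn.CohortConfig(
    n_control=30, n_patient=30, seed=7,
    affected_rois=tuple(range(10)), gmv_shift=1.0, coupling_drop=0.7,
)
subjects, manifest = szgcn.simulate_cohort(atlas, config)

spec = szgcn.GraphTypeSpec(90, "FBM", "sMRI+fMRI")   # sparsity 0.10
dataset = szgcn.build_dataset(subjects, spec, atlas)

ids = [s.subject_id for s in dataset]
model = szgcn.BrainGCN(
    dataset,
    szgcn.ModelConfig(hidden_dim=16),
    szgcn.TrainConfig(max_epochs=300, patience=100, seed=0),
)
res = model.fit(train_ids=ids[:25] + ids[30:55],
                test_ids=ids[25:30] + ids[55:])
print(res.summary())
print(res.top_salient(5).to_string(index=False))
```

prints (exact numbers depend on the seed):

```
Brain-graph GCN classification results
==============================================
graph type        N90:FBM&sMRI+fMRI@0.1
subjects          60 (train 50, test 10)
architecture      3 x (conv -> TopK pool -> readout), hidden 16, ratio 0.8
training          Adam lr 0.0001, batch 30, dropout 0.5
epochs run        300 (best validation loss at epoch 297)
----------------------------------------------
accuracy         1.000
auc              1.000
sensitivity      1.000
specificity      1.000
f1               1.000
precision        1.000
 roi_index roi_name  frequency  score  rank
         3  ROI_004         36  0.036     1
         8  ROI_009         36  0.036     2
         5  ROI_006         33  0.033     3
         0  ROI_001         31  0.031     4
         1  ROI_002         30  0.030     5
```

The planted signal (a 1-SD volume decrement plus a 0.7 coupling drop in
regions 0–9 of 90) is strong enough that held-out subjects separate
perfectly, and the most-selected regions of the last pooling layer are
exactly the affected ones.  A matched null cohort (both effect sizes
zero) stays at chance accuracy — see
`szgcn.experiments.recovery_experiment`.

A CLI mirrors the library (`szgcn simulate`, `features`, `graphs`,
`fit`, `evaluate`, `sweep`, `stats`); e.g.

```sh
szgcn stats --sex-counts 110 95 95 45 --summary 12.84 2.83 205 10.69 3.32 140
chi2 (Yates) = 6.379
Welch t = 6.264
```

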