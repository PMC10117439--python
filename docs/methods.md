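# Methods

## Problem and scope

`szgcn` implements a discriminative pipeline for two-group brain-MRI
cohorts (patients vs. controls): each subject is represented as a brain
graph whose nodes are atlas regions (ROIs) and whose edges come from one
of three connectivity constructions; a graph convolutional network with
TopK pooling classifies the graphs; and the pooling layers' node
selections are aggregated into a per-region saliency score.  Because
clinical MRI cohorts of this kind are not publicly shareable, the
package ships a seeded synthetic cohort generator so the entire pipeline
is testable end to end, and its headline validation is *parameter
recovery on phantoms*, not reproduction of clinical accuracies.

## Node features

Six per-ROI features, three structural and three functional:

* **GMV, WMV** — mean voxel gray-/white-matter value of the ROI.
* **ALFF** — each voxel series is linearly detrended, transformed with a
  real FFT, and the square root of the one-sided periodogram
  (`|X_k|^2 / n`) is averaged over the closed band 0.01–0.08 Hz (DC bin
  always excluded; band inclusion `low <= f <= high`).  Voxel values are
  divided by the subject's all-voxel mean (so normalised values average
  exactly 1) and averaged within ROI.  Detrending is standard ALFF
  practice; the band edges assume TR = 2 s (Nyquist 0.25 Hz).
* **ReHo** — Kendall's coefficient of concordance
  `W = 12 S / (K^2 (n^3 - n))` between a voxel and its within-block
  26-connected neighbours (truncated at block boundaries; the phantom
  has no global voxel lattice, so neighbourhoods never cross ROIs).
  Ranks use average-rank tie handling; a constant series raises an error
  by default (`constant="zero"` maps that voxel's W to 0).  Same global
  normalisation and ROI aggregation as ALFF.
* **sDC, fDC** — the row sum of the *weighted* structural/functional
  connectivity matrix.  Degree centrality is deliberately computed
  before binarisation: it is a node feature of the full connectivity
  pattern, while sparsification is a graph-input step.

## Edge constructions

* **GMM** (gray matter matrix): for each ROI the gray-matter voxel
  values are turned into a Gaussian-kernel density (Silverman bandwidth,
  128-point grid spanning the pooled range of the pair padded by 3
  bandwidths, floored at 1e-12 and renormalised); the edge weight is
  `exp(-[KL(p||q) + KL(q||p)])`, giving entries in (0, 1].  The
  exponential map of the symmetrised KL divergence is the standard
  construction in the morphological-similarity-network literature and
  the floor guarantees strictly positive aligned supports.
* **FBM** (functional brain matrix): absolute Pearson correlation of the
  ROI mean time series; entries in [0, 1].
* **GMM-FBM**: the two matrices min-max normalised separately over their
  off-diagonal entries and summed (entries in [0, 2]).  Min-max was
  chosen as the simplest map onto a common scale; z-scoring would be the
  obvious alternative and the normalisation is isolated in
  `minmax_offdiag` if a different convention is wanted.

**Proportional binarisation.**  The binary adjacency retains exactly
`k = round(p * N(N-1)/2)` undirected edges (round half away from zero),
chosen by descending weight; ties at the cut keep the lexicographically
smallest (i, j) pairs, so the retained count is exact and deterministic
even on degenerate weight matrices.  The Erdős–Rényi connectedness
heuristic `2 ln N / N` (0.100 at N = 90, 0.045 at N = 246) motivates the
default sparsities of 10% and 5%; binarising below the floor warns but
does not fail.

## Graph-type grid

Three node-feature selections (sMRI = GMV/WMV/sDC, fMRI = ReHo/ALFF/fDC,
sMRI+fMRI = all six, in that fixed column order) crossed with three edge
kinds give 9 graph types per atlas, 18 across the two default atlas
sizes.  Node features are z-scored per column, pooled across nodes and
training subjects only (one mean/SD per column, preserving between-ROI
contrasts); the scaler is refittable only once and is never shown
held-out data.

## Classifier

Three blocks of (graph convolution → TopK pooling → readout):

* convolution `H' = ReLU(D~^{-1/2} (A+I) D~^{-1/2} H W)`;
* pooling scores `y = H p / ||p||`, survivors the `k = ceil(0.8 N)`
  top-scoring nodes (ties by ascending index), features gated by
  `tanh(y)`, subgraph induced;
* readout = columnwise max ‖ columnwise mean.

The three readouts are summed and classified by a fully connected head
2h → h → 2 with ReLU and dropout 0.5.  Training uses Adam (lr 1e-4),
batch size 30, softmax cross-entropy, and early stopping on the loss of
an internal stratified validation split (15% of the training subjects),
patience counted in epochs since the last improvement; the
best-validation weights are returned.  Everything is implemented in
NumPy with hand-derived gradients (verified against finite differences
in the test suite); gradients flow through the tanh gate and the
retained nodes' scores only, as the selection itself is discrete.

Open architecture choices (layer widths, pooling ratio, batch-norm
placement, the early-stopping monitor) are recorded in `ModelConfig` /
`TrainConfig` defaults: hidden width 64, pool ratio 0.8 (which leaves
47 survivors at N = 90 and 126 at N = 246 — the saliency procedure
needs at least 20), batch norm after the first FC layer, validation
loss as the monitored quantity.

**Projection-vector initialisation.**  Weights use uniform fan-in
initialisation; the pooling projection vectors `p` are initialised
*non-negative* (`U(0, 1/sqrt(h))`).  Node activations are non-negative
after ReLU, so a non-negative projection makes the initial pooling
scores rank nodes by activation magnitude.  With a sign-symmetric
initialisation the selection orientation is a coin flip between two
equally well-classifying optima — one that retains the most atypical
(informative) nodes and one that drops them — and in the latter the
selection-frequency saliency points away from the discriminative
regions.  On planted-signal phantoms, symmetric initialisation
recovered on average 4 of 10 planted regions in the top-10 saliency
ranks across repeated splits (individual runs landing at 0 or 10),
while non-negative initialisation recovered 10 of 10 with identical
classification accuracy.

## Saliency

For each training subject, one deterministic forward pass records the 20
highest-scoring survivors of the third pooling layer ("first 20" =
top-scored, the only ordering the algorithm defines; ties by ascending
node index).  A region's score is its selection count divided by
20 × n_train, so scores sum to 1 and are bounded by 1/20 (e.g. 300
training subjects give the denominator 6,000).  Saliency uses the final
best-validation weights, with dropout off and batch statistics frozen.

## Evaluation protocol

Stratified random train/test splits at a 300:345 proportion, repeated
(10 by default) with per-repeat seeds derived from one master seed; six
metrics with the patient class positive: accuracy, rank-based
(Mann–Whitney) AUC with half-credit ties, sensitivity, specificity,
precision, F1 (undefined ratios reported as missing, never coerced to
0).  The sparsity sweep re-thresholds the cached weighted matrices on a
5–50% grid in 5% steps and repeats the whole evaluation per point.

The two demographic statistics reproduce the published cohort table
from its printed summaries: Welch's unequal-variance t (the pooled form
does not match the printed education statistic; Welch does) and the
Yates continuity-corrected chi-square (the uncorrected form does not
match the printed sex statistic; the corrected one does).

## Synthetic cohort generator

Per subject, each of N ROIs is a 3×3×3 voxel block.  Functional side:
ROIs are assigned round-robin to 5 communities (`community = roi mod
5`); each community has a latent signal — white noise smoothed by a
5-point moving average (band-limiting power into 0.01–0.08 Hz at
TR = 2 s so ALFF is meaningful) and restandardised to unit variance; the
ROI mean series is `lambda * s_c(t) + eps` with temporal noise SD 0.5,
and voxel series add independent voxel noise (SD 0.5).  These scales
give within-community |r| ≈ 0.8 for controls — a realistic
resting-state coupling magnitude.  Structural side: voxel tissue values
are Normal(mu_r, 0.1) with per-ROI baselines mu_r ~ Uniform(0.4, 0.8)
drawn once per cohort and shared by both groups (stable cross-subject
ROI identity, so KL similarity is structured rather than pure noise);
these hyperpriors are inventions, labelled as such in the cohort
manifest.

Group effects are planted in a configurable ROI subset of patients: a
gray-matter mean decrement of `gmv_shift` SD units, and a community
loading reduced to `1 - coupling_drop` (0.7 drops within-community |r|
to ≈ 0.45).  With both effects zero the two groups' generative
distributions are identical by construction.

What the phantom does **not** emulate: anatomy and spatial registration,
scanner artifacts and head motion, hemodynamics, inter-subject
variability structure beyond independent noise, and cross-ROI voxel
adjacency.  Passing recovery tests therefore shows the pipeline
correctly extracts planted statistical structure of this kind — not
that it would reach any particular accuracy on clinical data.

## Recovery experiment and problem sizes

The headline experiment plants the signal in 10 of 90 ROIs
(coupling drop 0.7, GMV shift 1.0 SD) in a 60 + 60 cohort and evaluates
the FBM & sMRI+fMRI graph type over 10 repeated splits; the matched
null cohort (same sizes, zero effects) must stay inside the 95%
binomial chance band.  Desk-scale model settings — hidden width 16,
300–600 epochs with patience 100–150 — train one repeat in seconds on a
single CPU while leaving the optimisation protocol (Adam 1e-4, batch
30, dropout 0.5, early stopping) unchanged.

## Known limitations

* The saliency construction counts node *selections*, so it can only
  surface regions the trained pooling chooses to retain; a network is
  free to classify by dropping the most atypical nodes instead, in
  which case selection-frequency saliency points away from the
  discriminative regions.  The recovery experiment probes exactly this;
  the non-negative projection initialisation (above) is what anchors
  training in the retain basin.
* Spectral-leakage effects make ALFF only approximately invariant to
  out-of-band signal; the band is treated as a closed interval of DFT
  bins, so very short series raise an error naming the minimum length.
* The KL-similarity matrix is dense in O(N^2) kernel-density
  evaluations; the vectorised implementation handles N = 246 in
  seconds, but memory grows with the pair-chunk size.
* Binary graphs only; weighted-graph classification is out of scope.
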