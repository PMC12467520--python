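# Methods

## Overview

`neurofuse` classifies subjects of a two-class neuroimaging cohort
(e.g. autism spectrum disorder vs. typically developing controls) by
fusing three kinds of evidence:

1. **Volumetric features.** Structural MRI and temporally collapsed
   functional MRI volumes pass through an adaptive convolutional feature
   extractor: stacked 3D convolution blocks, each refined by
   squeeze-excitation channel attention and a CBAM-style spatial
   attention map, with an identity residual skip around the attention
   pair, followed by adaptive average pooling and a ReLU projection to a
   fixed-width embedding.
2. **Brain-graph features.** For each atlas, ROI time series become an
   undirected brain graph: nodes are regions plus one appended
   average-signal node, node features are Pearson correlation profiles,
   and edges combine bilateral homolog links, average-node links and a
   top-K functional-connectivity kNN term. An edge-sensitive pooling
   mechanism scores each node with a sigmoid importance coefficient
   α = σ(Hw) from a spectral graph convolution H = ReLU(ÂXW), scores
   each undirected edge as e_ij = α_i + α_j, prunes edges whose score
   does not strictly exceed the mean edge score (all nodes preserved),
   and mean-pools a second convolution on the sparsified graph into a
   per-atlas embedding.
3. **Phenotypes.** Site and sex (one-hot) and age and IQ (z-scored)
   enter the population-graph node vectors alongside the fused imaging
   embedding.

A shared/private fusion module processes each modality embedding with
one shared encoder (a single parameter set reused across modalities) and
a per-modality private encoder, mixes the two through an elementwise
sigmoid gate, f_m = g ⊙ s_m + (1 − g) ⊙ p_m, concatenates the fused
vectors and projects them through a ReLU linear head. Subjects then form
one population graph — edges join pairs whose block-normalised node
vectors have absolute cosine similarity above a threshold `th` — and a
two-layer graph attention network classifies nodes transductively.
Between the layers, dynamic attention-based pruning ranks all directed
edges by their layer-1 attention coefficients and keeps exactly
⌈p/100 · |E|⌉ of them, re-inserting one self-loop per node. The loss is
binary cross-entropy summed over the training mask plus λ·Σ‖W‖² over
the weight matrices.

## Training staging

Per-subject feature extraction (volumetric extractor, edge-sensitive
pooling) runs once, ahead of classifier training, in batches of 32
subjects; the extractors are seeded, randomly initialised forward passes
in the randomized-features tradition. This staging mirrors deployments
where features and graphs are prepared before population-level
reasoning, keeps the expensive convolutional stage out of the training
loop, and is sufficient here because random convolutional and spectral
projections preserve linear class structure (a linear probe on the
extracted features of a planted-signal cohort is essentially perfect).
The fusion module and the graph attention classifier are trained
jointly, end to end, by Adam (learning rate 1e-3) on the masked loss.
The population graph is built once per fold from the initialisation-time
fused embeddings plus phenotypes; it is not re-thresholded during
training (only the attention-based pruning between the GAT layers is
dynamic).

## Prediction is the Monte Carlo dropout mean

Dropout (rate 0.5) is applied to the attention coefficients and hidden
features of both GAT layers during training and doubles as the
uncertainty machinery: predictions are the mean of `mc_passes`
(default 20) stochastic forward passes with dropout active, and the
per-subject standard deviation over passes is the uncertainty estimate.
The single deterministic forward (dropout off) exists and is exactly
reproducible, but it is *not* the calibrated output of a network trained
under this much stochasticity: dropout inflates the variance of
pre-activations, ReLU converts that variance into a positive mean shift,
and downstream weights adapt to it, so the deterministic pass
systematically shrinks the logits (we observed folds with near-perfect
ranking whose deterministic 0.5-thresholded accuracy was at chance).
Validation-loss checks during training use the same Monte Carlo mean
(4 passes, every second epoch) so that model selection and prediction
see the same statistics.

## Cross-validation and early stopping

Evaluation is stratified k-fold (default 10; the desk-scale acceptance
configuration uses 5) realised as masks on the single population graph —
all subjects participate in message passing, only training-mask subjects
contribute loss. Within each fold, 10% of the training mask (stratified)
is held out for early stopping: training runs up to `epochs` (default
200) and stops when the validation loss has not improved for `patience`
epochs (default 20), with a burn-in of `min_epochs` (default 60) before
the patience countdown starts — without the burn-in, the flat early
plateau of attention-network optimization triggers spurious stops. The
best-validation parameter state is restored before evaluation. Metrics
(accuracy, sensitivity, specificity from the 0.5-thresholded confusion
table, ties predicted positive; AUC from the ROC curve) are reported per
fold and aggregated as mean ± SD across folds.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `embed_dim` (d) | 64 | per-modality embedding width; all five modalities share it so concatenation is well-formed |
| `reduction_ratio` (r) | 8 | squeeze-excitation bottleneck; must divide each conv block's channel count |
| `acfe_channels` | (8, 16, 32) | conv block widths, small enough for CPU batches of 32 |
| `knn_k` | 10 | functional-connectivity neighbours per node added to the rule-based edge set |
| `similarity_threshold` (th) | 0.5 | population-graph binarization threshold on absolute cosine |
| `prune_percent` (p) | 70 | % of directed edges kept by attention pruning between GAT layers |
| `gat_hidden` / `gat_heads` | 64 / 4 | layer-1 width (split across heads, concatenated) |
| `dropout` | 0.5 | on attention coefficients and hidden features; the MC-dropout site |
| `weight_decay` (λ) | 5e-4 | L2 penalty weight in the loss |
| `lr`, `batch_size` | 1e-3, 32 | Adam step size; feature-extraction batch |
| `mc_passes` | 20 | Monte Carlo dropout passes for prediction/uncertainty |

## Synthetic cohorts

The generator produces the statistical structure the model assumes,
with one explicitly threaded seeded generator and no global state:

* **Volumes** are unit-SD Gaussian noise plus a spherical blob at a
  fixed location whose intensity is `blob_contrast` (in noise SDs) for
  class 1 and absent for class 0; functional volumes put the blob at a
  different fixed location, constant over frames, with independent
  per-frame noise so the temporal-mean collapse recovers it.
* **ROI time series** follow a latent-factor model: homolog pairs are
  split into two modules, region i in module m follows
  z_m + ρ_c·z_other + b·u_pair + ε with cross-module loading
  ρ_c = ρ + Δr·label (defaults ρ = 0.2, Δr = 0.4, bilateral loading
  b = 0.6, noise SD 1), so class 1 couples the modules more strongly and
  left/right homologs correlate above background.
* **Phenotypes**: sites optionally class-correlated (default
  independent), sex balanced, ages uniform 7–40, IQ normal(105, 15).

Desk-scale geometry is 16³ volumes, 20 regions per hemisphere per atlas,
two atlases, T = 60 time points. The generator does **not** emulate BOLD
autocorrelation spectra, scanner artifacts, registration error or
site-specific intensity scaling, so passing the planted-signal check
shows the architecture can recover class structure of the assumed form —
it says nothing about effect sizes or confounds in real multi-site
cohorts.

## Numerical choices

* All differentiable computation runs on a small reverse-mode autodiff
  engine over numpy float64 arrays; gradients were verified against
  central finite differences on every attention-layer parameter.
* Neighborhood softmax subtracts the per-destination maximum (a
  constant shift that cannot change the softmax or its gradient) for
  overflow safety; scatter/gather adjoints use sparse incidence
  matrices.
* Edge pruning ties: the mean-score rule uses strict `>`; if no edge
  survives (all scores equal) every edge is retained. Attention-ranked
  pruning breaks ties toward higher attention then lower (source,
  target) index, and counts directed edges; self-loops are never ranked
  and are re-inserted after pruning.
* Predicted probabilities are clamped to [1e-7, 1 − 1e-7] inside the
  loss; the clamp passes gradient only inside the bounds.
* Zero vectors in cosine similarity define similarity 0 (logged);
  constant ROI time series raise a feature error instead of producing
  undefined correlations.
* Biomarker ranking averages α per ROI over subjects, excludes the
  average-signal node, sorts descending and breaks ties by ROI index.
* 4D functional volumes collapse to 3D by voxelwise temporal mean
  (config alternative: temporal SD).

## Open design points resolved

* Whether structural and functional volumes share extractor weights is
  configurable (`share_acfe_weights`); default separate.
* The concatenated pre-fusion matrix X is exported as a diagnostic
  (`FeatureBundle.concatenated`) but not consumed by the gated fusion,
  whose inputs are the per-modality embeddings.
* The gate is a per-dimension vector by default (`scalar_gate` gives the
  scalar variant).
* Attention pruning counts directed edges (documented above);
  the loss sums over the training mask only.
* Printed real-data edge counts for the standard atlases are not
  reproducible from the stated construction rules alone; the kNN term's
  K is therefore exposed as configuration rather than fitted to those
  totals.

## Known limitations

* The volumetric and brain-graph extractors are not trained through the
  classification loss; with weak or highly nonlinear class signal their
  random projections may lose information a jointly trained extractor
  would keep.
* Full-graph transductive training is O(edges) per epoch in dense
  numpy; cohorts beyond a few thousand subjects would need minibatched
  neighbor sampling.
* The deterministic forward under-confident behaviour described above
  means downstream consumers should use `FoldModel.predict` (MC mean),
  not a single dropout-free pass, when thresholding probabilities.
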