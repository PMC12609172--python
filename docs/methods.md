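# Methods

## Problem and labeling model

A sample is a triplet *(drug 1, drug 2, cell line)* with a continuous
synergy score from a combination screen. Scores strictly above 30 are
labeled synergistic, scores strictly below 0 antagonistic; the band
[0, 30] is treated as inconclusive and removed **before** any vote, so only
positive/negative calls participate in conflict resolution. Replicated
measurements of the same unordered pair on the same cell line are resolved
by strict majority vote; an exact tie leaves the triplet out of the
dataset, since neither label has majority support. Pairs are canonicalized
with the lexicographically smaller drug identifier first; optional order
augmentation duplicates each triplet with the drugs swapped (same label),
which both enlarges the training set and encourages order-invariant
predictions.

## Featurization

- **Fingerprints.** ECFP6 = Morgan circular fingerprints with radius 3
  (diameter 6), folded to 1024 bits (RDKit). Unparseable SMILES drop the
  drug with a logged warning rather than aborting a whole panel.
- **Tanimoto profiles.** Each drug's numerical descriptor is its vector of
  Tanimoto coefficients |A∩B|/|A∪B| against a fixed, ordered reference
  panel; two empty fingerprints are defined to have similarity 0. By
  default the panel is the dataset's own drug panel (so each drug carries a
  1.0 at its own position). For leave-drug-out experiments the panel can be
  frozen to the training-split drugs via `build_dataset(reference_panel=…)`
  so unseen drugs receive profiles of the fitted length; the default
  experiments use the full panel, which fixes the feature dimension without
  per-fold refits.
- **Expression.** Per-gene z-scores with the population standard deviation,
  computed over all available cell lines before subsetting; constant genes
  map to zero (deterministic and degeneracy-safe). The transformation is
  idempotent.

## Architecture

Widths follow the reference configuration: embedding width E = 512 per
field, FM/DNN output width K = 1024, hidden DNN 512×1024, prediction hidden
layer 512, dropout 0.5, Adam at 10⁻³ with step decay (×0.95 every 10
epochs by default), batch 256. The desk-scale experiments in this
repository use a proportionally reduced model (E = 32, K = 64, widths
48×64, hidden 64, dropout 0.1) — the architecture is identical, only the
widths shrink. Choices the printed equations leave open were fixed as
follows:

- **Activations.** σ is the sigmoid wherever the equations print σ (hidden
  DNN, head projection, both head dense layers — including the sigmoid
  applied to the logits *inside* the final softmax). The numerical feature
  extractor's nonlinearity is not pinned by the equations; it uses ReLU,
  which also preserves the zero input → zero output contract used in
  testing.
- **Flattening order.** After the embedding-aware stage the streams are
  transposed back and flattened field-major, so each consecutive E-block of
  the 6E vector belongs to one field. Any consistent order would do (the
  downstream layers are learned); consistency is the contract.
- **Head residual.** The second DSA in the prediction head has independent
  parameters and operates on the six natural E-wide blocks of the DSA
  output x (stream one) and the projected FM/DNN fusion x̃⁽¹⁾ (stream
  two). Batch normalization uses running statistics in eval mode
  (momentum 0.1, ε = 10⁻⁵). Dropout sits after each hidden DNN layer and
  after x̃⁽¹⁾.
- **Initialization.** Glorot-uniform per dense layer, N(0, 0.05²) for the
  embedding table, all drawn from the configured seed; training is fully
  deterministic given the seed.
- **Loss.** Mean of −w(y)·log p(y) with probabilities clamped at 10⁻⁷;
  unweighted by default, w = (2.3, 1) in the class-weighted mode.
  Early stopping monitors validation AUC-ROC (patience 10, max 100 epochs
  by default).

## Ablation variants

Ten named variants are derived from the shared configuration by switches:
single-stream (`cat`, `aux`), attention replaced by concatenation
(`w/o-attn`), reversed stage order (`attn-rev`), single stages
(`attn-field`, `attn-emb`), one sigmoid gate with residual over the
concatenated 6E vector (`attn-unified`, scores deliberately not normalized
across streams), per-dimension softmax gating of the FM/DNN outputs with
sum or concatenation (`gated-sum`, `gated-concat`), and a plain three-layer
dense head consuming [x, x̃⁽¹⁾] ∈ ℝ¹²ᴱ in place of the attention residual
(`w/o-res`, widths 12E→512→128→2, configurable). For paired attention
comparisons `run_ablation(exclude_residual=True)` switches every model —
including `full` — to the dense head, so attention effects are not
confounded with the residual mechanism.

## Evaluation

Eight metrics: AUC-ROC (tie-corrected rank statistic), AUC-PR (average
precision), accuracy, precision, recall, F1, Cohen's κ = (p₀−p_e)/(1−p_e),
and balanced accuracy (TPR+TNR)/2, implemented in-package and cross-checked
against scikit-learn to 10⁻⁸ in the test suite. Class metrics use threshold
0.5; candidate discovery uses 0.6. Single-class test sets flag the AUCs as
undefined instead of failing.

Four split regimes, five folds each, realizing the 3:1:1 ratio as
test = fold f, validation = fold f+1, train = the rest. All regimes split
over canonical unordered-triplet keys so a pair and its swapped duplicate
never straddle partitions. Leave-cell-line-out/leave-tissue-out/
leave-drug-out group by the respective entity; in leave-drug-out a triplet
is assigned to test if either drug is a test-fold drug and trains only on
all-train-drug pairs, so every test pair contains at least one unseen drug.
In the leave-out regimes embeddings can be frozen at initialization
(`freeze_embeddings`), since held-out entities would otherwise carry
untrained rows.

## Synthetic benchmark

The generator emulates the statistical shape of curated combination
screens, not their chemistry or dose-response biology:

- Drugs belong to `n_drug_clusters` (default 4) latent clusters; a cluster
  shares a fingerprint template (bit density 0.1) perturbed by per-drug bit
  flips (rate 0.02), so within-cluster Tanimoto similarity exceeds
  between-cluster similarity, and latent factors u are cluster centers plus
  noise. Cell lines inherit a tissue-level latent center (round-robin
  tissue assignment) plus noise; expression is a fixed linear read-out of
  the cell latent factors, so `noise_sd = 0` makes tissue-mates identical.
- The continuous score is s(i,j,k) = strength·(uᵢᵀM uⱼ + wₖ·(uᵢ+uⱼ)) + ε
  with M symmetric and one noise draw per **unordered** triplet, so the
  surface is exactly drug-order symmetric and order-consistency tests have
  a well-defined target. An affine calibration on a pilot sample of 10,000
  triplets places the 0/30 thresholds so the negative:positive ratio
  matches the target (default 2.3, the imbalance typical of curated
  screens) with a small mid band (5%) exercising the exclusion rule.
- Defaults (m = 40 drugs, n = 8 cell lines across 4 tissues, 60 genes,
  latent dimension 6, interaction strength 3, noise SD 0.3, 4,000 sampled
  triplets) define the standard recovery benchmark: strong pairwise latent
  structure, modest noise — conditions under which a correct implementation
  should separate the classes well while a label-permuted null stays at
  chance. Passing on this benchmark demonstrates the pipeline learns
  order-symmetric pairwise structure; it does **not** certify performance
  on real screens, whose fingerprint-synergy relationship, expression
  noise, replicate structure and assay batch effects are far richer.

## Reference experiment and problem sizes

`dsadeepfm.experiments.run_recovery_experiment` trains the reduced model on
the default benchmark (one random-CV fold, ~4,600 training triplets after
augmentation, 15 epochs maximum), the categorical-only ablation and a
label-permuted null under the identical split, then computes
order-consistency (Pearson between swapped-order predictions) and
class-separation statistics (cosine geometry after per-dimension z-scoring
and L2 normalization: mean intra-class pairwise distance averaged over
classes, distance between re-normalized class centroids, their margin and
ratio) at the initialized-embedding and pre-prediction stages. These sizes
were chosen as the smallest at which the benchmark's signal is
comfortably learnable; they are the package's standard configuration, used
by both the test suite and `scripts/acceptance.py`. A 2-D t-SNE export
(perplexity 30, fixed seed) is provided for visualization only; the
separation statistics are the tested surface.

## Known limitations

- No GPU path and float64 only; the full-width configuration (E = 512,
  K = 1024) trains slowly on CPU and is intended for completeness, not
  routine desk use.
- The KEGG-pathway/drug-target resources sometimes curated alongside such
  screens are not part of the feature pipeline; gene-panel filtering is
  available via `build_dataset(gene_subset=…)` but no default filter is
  applied.
- The pipeline treats `synergy_score` as a single given column; it does not
  distinguish Loewe/Bliss/ZIP/S conventions.
- Raw-score regression, competitor model reimplementations and external
  database parsers are out of scope.
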