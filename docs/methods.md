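# Methods

## The model

`microsig` treats signature discovery as attention attribution in a
node-classification problem on a heterogeneous graph.

**Graph.** Two node sets: species and samples. Edge types:

* abundance (species↔sample): one edge per nonzero cell of the TSS-normalized
  matrix, weighted by relative abundance; both directions are materialized so
  messages flow species→sample and sample→species;
* metabolic (species↔species): species sharing any compound in the
  interaction table, with per-pair multiplicity equal to the number of shared
  compounds (kept as annotation; the default model treats the edge as
  unweighted). Interaction direction (production/consumption/degradation) is
  ignored for edge formation — the shared compound is what links the pair —
  and retained for export. Non-species entries of the table (e.g. host cell
  types) never become nodes;
* phylogenetic (species↔species): same-genus pairs, a clique per genus.

**Features and initial embeddings.** A species' raw feature vector is its
relative abundance across samples; a sample's is its composition across
species. One variational autoencoder per node type (single hidden layer of
width `n_hid`, tanh; Gaussian latent; loss = reconstruction MSE +
`kl_coef`·KL) is fit on globally standardized features for `ae_epochs`
epochs, and the posterior mean gives each node a 256-dimensional initial
embedding. A variational latent is used because a KL coefficient is only
meaningful for a distributional code; with `kl_coef = 5e-5` the KL term is a
mild regularizer, not an information bottleneck. The embedding may be wider
than the feature dimension (over-complete); this is logged, not an error.

**Attention layers.** Initial embeddings are projected to `n_hid = 128` and
passed through `n_layers = 2` residual attention blocks with `n_heads = 8`.
Per layer: type-specific Q/K/V projections; per relation, per-head key and
message transforms plus a learned scalar prior; scaled dot-product logits are
softmax-normalized over each target node's full incoming neighborhood, per
head. Abundance edges add log(weight) to their logit as a fixed offset, so a
sample's attention over its species starts out proportional to relative
abundance and training reweights it. This is where the abundance edge weight
enters the model; without it the classification objective can be satisfied
entirely through the residual path and species→sample attention never
localizes on discriminative species. Output: residual + ELU-activated linear
per node type.

**Objective and schedule.** A linear head classifies sample nodes by cancer
type with focal loss (γ = 2 by default; γ = 0 recovers cross-entropy
exactly). Adam at lr 0.003, 50 epochs, full batch; the lr is multiplied by
0.5 when validation macro-F1 (stratified 20% split of sample nodes) fails to
improve for 5 consecutive epochs (counter resets after each reduction).
Training aborts on non-finite or exploding (>1e6) loss. Only sample nodes
carry a supervised objective; species nodes are shaped by message passing
and the autoencoder initialization. Everything is NumPy with hand-derived
gradients, checked against finite differences in the test suite;
segment-softmax bookkeeping goes through a precomputed sparse incidence
matrix. Runs are bit-reproducible for a fixed seed on a fixed platform
(single deterministic RNG; no stochastic minibatching).

**Attention extraction.** Species→sample attention is averaged over heads
and, by default, over both layers (`attention_aggregation = "mean_layers"`;
`"last"` gives final-layer-only). Layer averaging was adopted because each
layer provides a noisy view of species relevance and the average is visibly
less noisy than either layer alone. Non-adjacent pairs score 0.

## Signature calling

For each species i, a sample s is *high-attention* when

    α(i, s) > THRES × mean over {s′ : α(i, s′) > 0} of α(i, s′),   THRES = 3.

Zeros are structural absences (the species is not in the sample), so the
reference level is the species' mean attention where it occurs; the cutoff
reads as "3-fold its typical attention". An alternative `zscore` mode flags
α(i, s) > mean_i + THRES·sd_i over all samples. The fold-change rule is the
default because a class-specific signal occupying a quarter of all samples
saturates near z ≈ √((1−f)/f) ≲ 2.6 and mean+3·sd can never flag it, while
heavy-tailed null species still accrue enough z-flags for the discrete
hypergeometric tail to reject at roughly the nominal rate; the fold-change
rule flags the entire elevated block of a signal species but typically ≤2
samples of a null species — below the smallest count that can reach
p < 0.05 — which keeps the uncorrected test conservative.

Counting k high-attention samples inside the type (n of N samples, K flagged
overall) gives the hypergeometric upper tail; p < α = 0.05, uncorrected,
defines the signature, matching the convention of reporting raw p-values at
0.05 in this setting. Benjamini–Hochberg is available (`correction="bh"`), as
is a binomial test. All (cancer type, species) pairs are tested; types with
fewer than 2 samples are skipped. `normalized_attention` (reported per
record and used as edge weight in exports) is the species' mean attention
within the type, min–max scaled within the type.

## Synthetic studies

The generator emulates the statistical structure the method assumes, not any
particular cohort: per-cell intensity exp(μ_i + σ_cell·z) with species
baselines μ_i ~ N(log 20, 1) and σ_cell = 0.5, thinned by 50% structural
zeros and rounded to counts (a negative-binomial option exists). Planted
species (5 per type by default) have intensity ×8 in samples of their target
type. Genera are assigned uniformly at random; species-compound incidence is
Bernoulli(0.08), and each planted block is guaranteed one shared compound so
the relation-edge machinery participates in recovery runs. Balanced types,
disjoint planted sets, fully deterministic per seed.

Calibration rationale: sparsity and noise were chosen so that the ×8 planted
effect produces the regime the recovery benchmarks presuppose — classes
separable (a logistic-regression baseline on raw compositions reaches
0.65–0.90 accuracy; at 50% sparsity the chance that a target-type sample
contains none of its 5 planted species is ~3%) and planted species
recoverable by a plain mean-abundance contrast. The cell-level noise
(σ = 0.5) reflects data that have already passed conservative
decontamination and batch correction upstream. These values were fixed once
and the benchmarks report whatever they produce.

What the generator does **not** emulate: taxonomic correlation structure
(real genera share abundance patterns), compositional coupling beyond
closure, batch effects, varying sequencing depth, and curated interaction
databases' bias toward well-studied taxa. Passing recovery tests therefore
demonstrates the machinery works under the stated statistical structure, not
performance on clinical data.

Measured behavior at the default conditions (120×300, 4 types, ×8, 50
epochs; seeds 1–3): sensitivity for planted (type, species) pairs 0.95–1.0;
false-discovery proportion vs the planted truth 0.09–0.21 (median ≈ 0.17);
with the effect off, ≤1% of pairs reach p < 0.05. Seed-to-seed variance is
real: occasional seeds amplify chance type-correlations of unplanted species
through the trained attention and FDP can exceed 0.4 (validation accuracy
stays ~0.85–0.97); the abundance-only analogue of the flag rule shows FDP
0.0–0.26 on the same draws, so the excess is attention noise, not a
statistics defect. Validation accuracy runs 0.85–0.97 against a 0.25
majority baseline.

## Numerical choices and degenerate inputs

* TSS requires strictly positive sample totals; zero-total samples are a
  hard error naming the samples.
* The prevalence filter compares within-sample relative abundance to the
  threshold with ≥, is scale-invariant per sample, and `threshold=0` is the
  identity. Alternative readings of the cutoff (`grand_total`,
  `prevalence`) are config options.
* Chao1 uses S_obs + F1²/(2F2), switching to the bias-corrected form when
  F2 = 0; ACE uses the standard rare cutoff of 10 and falls back to
  bias-corrected Chao1 when every rare taxon is a singleton (where ACE is
  undefined). Both require integer counts; Shannon is reported in nats.
* Focal loss clamps p_t at 1e-12; the γ < 1 singularity at p_t = 1 is
  guarded.
* Softmax logits are stabilized by per-segment maxima; species with zero
  attention spread flag nothing; min–max scaling of a constant vector
  returns zeros.
* Ties in signature ordering are broken by taxid (stable sort), making
  output files byte-reproducible.
* File round-trips use shortest round-trip float formatting and
  `float_precision="round_trip"` parsing, so staged runs (each stage re-read
  from TSV) reproduce the in-memory pipeline exactly.

## Problem sizes

Tests and the reproduction script run the full study at 120 species × 300
samples (the scale at which the planted-recovery properties are stated) and
smaller graphs elsewhere; training is a few dozen seconds per run on one
CPU. The real-data regime (thousands of species and samples) is within reach
of the same code but was not benchmarked here.

## Known limitations

* Attention is associational: a high score means the species is strongly
  represented in samples of the type, not that it causes anything.
* The raw-p significance rule (no multiple-testing correction by default)
  follows the published convention it mirrors; with many species and types,
  users wanting family-wise control should pass `correction="bh"`.
* Single fixed architecture depth/width; no hyperparameter search is
  performed by the package.
* The z-score flag mode is retained for completeness but is a poor match
  for signals present in a large fraction of samples (see above).
* Name→taxid mapping is exact case-insensitive matching; synonyms and
  strain-suffix variants are dropped rather than resolved.
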