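# Methods

## The model

`smirtd` implements one-class adverse-drug-reaction (ADR) risk scoring with a
replaced-token-detection (RTD) chemical language model. Two transformer
encoders share a token/position embedding table:

* the **generator** is a masked language model (MLM): given a SMILES sequence
  with a fraction *m* of its tokens masked, it predicts the original token at
  each masked position;
* the **discriminator** receives the sequence with each masked position
  filled by a *sample* from the generator's distribution, and classifies
  every token as *original* or *replaced* (a token is "original" when the
  generator happened to reproduce it — the standard RTD convention).

Both encoders are pre-norm transformer blocks (multi-head scaled dot-product
attention, GELU feed-forward, learned absolute positions, final layer norm);
the generator is a narrower copy (`generator_width_fraction`, default 1/2,
study preset 1/4) whose MLM scores are tied to the shared embedding table.
The joint loss is `L_MLM + λ·L_disc` with λ = 50, optimized with Adam. The
whole stack — including reverse-mode autodiff — is implemented in NumPy
(`smirtd._autograd`), which keeps the package dependency-light and fully
deterministic per seed on CPU.

**Training is one-class:** only drugs that *have* the ADR enter training
(`train` raises on any label-0 record). The discriminator therefore fits the
token-context distribution of the positive class only.

## Scoring and calibration

At inference a clean (uncorrupted) SMILES is passed through the
discriminator. A token is *flagged* when its replaced-probability exceeds a
token threshold, set equal to the training masking ratio by default. The
drug-level score is the replaced-token fraction

    probability = 100 · (flagged tokens) / (molecular length in tokens),

a dissimilarity score: molecules from the training distribution have mostly
"original"-looking tokens (low score); molecules from a different chemical
distribution trigger flags (high score). Special tokens never enter numerator
or denominator.

The drug-level decision threshold is calibrated on labeled validation scores
by maximizing Youden's J = sensitivity + specificity − 1 over candidate
thresholds (midpoints of consecutive distinct scores plus ±∞ sentinels; ties
resolve to the smallest maximizing threshold). A drug is predicted positive
(has the ADR) when its score is strictly *below* the chosen threshold.

## Dataset partitioning

Labeled tables are split with the one-class protocol: positives 8:1:1 into
train/validation/test (floor rounding for the two small parts, remainder to
train); negatives — never trained on — split evenly between validation and
test, then randomly down-sampled by a per-dataset `negative_keep_fraction`
(floor rounding) to balance the evaluation classes. Training positives are
augmented by SMILES enumeration (randomized atom-order traversal,
deduplicated; study preset 6 strings per molecule) once, up front.

## Evaluation

Nine metrics: accuracy, recall, precision, MCC, balanced accuracy, F1,
specificity (direct confusion-matrix arithmetic), AUROC and AUPRC
(scikit-learn; AUPRC is step-interpolated average precision, deliberately
not trapezoidal). Zero-denominator conventions: precision = 0 with a warning
when nothing is predicted positive; MCC = 0 when a denominator factor is 0.
The positive class is always "has the ADR".

External pharmacovigilance validation uses the proportional reporting ratio
PRR = (NTT/NAT)/(NTA/NAA) with the 95% CI
`exp(ln PRR ± 1.96·√(1/NTT − 1/NAT + 1/NTA − 1/NAA))`. Zero cells raise by
default (a Haldane +0.5 correction is opt-in), drugs with PRR < 1 are
filtered, duplicates and training-set overlaps are removed by canonical
SMILES, and the ranked-recall curve reports the predicted-positive fraction
among the top-10k drugs by descending PRR (final partial group included).

## Explainability

Per-token salience is the mean attention a token *receives* (column mean),
aggregated over heads of the final discriminator layer by default
(attention-rollout across layers is available). Non-atom tokens (digits,
brackets, bonds) fold their salience into the nearest preceding atom, so all
salience lands on the molecular graph; highlighted substructures are
connected atom sets above the 0.75 salience quantile. Embeddings for
projection (t-SNE/UMAP via standard tooling) are the final encoder layer
mean-pooled over tokens.

Salience profiles are not guaranteed invariant across enumerated SMILES
variants of the same molecule: attention is computed on the token sequence,
and different traversals present different contexts. The package always
scores and explains canonical SMILES for this reason.

## The synthetic test bed

`smirtd.synthetic` generates planted-motif datasets that emulate the
one-class structure the method assumes. Molecules are assembled from a
congeneric-series template — head + 1–3 linkers + tail, every fragment a
valid SMILES chain continuation — mirroring how drugs in a chemotype family
share scaffold chemistry. Positives always contain at least one
structural-alert motif (default: tertiary amine, aryl halide — alerts with
large published prevalence differences between QT-prolonging and
non-QT-prolonging drugs); negatives use motif-free linker chemistry
(secondary amines, ethers, esters). Heads and tails overlap between classes
and the token vocabulary is fully shared, so separation requires context
rather than vocabulary lookup. Class purity is verified by substructure
matching on every molecule; generation is deterministic per seed.

Two design facts, learned the hard way and worth stating:

* a one-class RTD detector can only flag the *presence* of unfamiliar
  patterns, never the *absence* of familiar ones — negatives must carry their
  own characteristic chemistry, as real non-ADR drugs do, or they are
  undetectable in principle;
* the grammar must be low-entropy enough for the MLM to learn. An iid
  random-fragment soup has ~1.7 nats/token of irreducible uncertainty, which
  drowns the replaced-token labels in noise; the template grammar mirrors the
  internal regularity of real drug series.

What the test bed does **not** emulate: real pharmacological class imbalance
and label noise, stereochemistry and charged species, the long-tail
vocabulary of curated datasets, and any biological mechanism. Passing the
synthetic experiments demonstrates that the pipeline's machinery works as
specified under the stated one-class assumptions — not clinical performance.
Reproducing the published curated-dataset AUROCs additionally requires those
external datasets and unreported hyperparameters, and is out of scope.

## Study-scale configuration and problem sizes

The package-wide defaults keep conventional stand-ins (d_model 128, 4 layers,
4 heads, FFN 256, max length 256, 200 epochs, lr 2·10⁻⁴). The package's own
experiments use the `smirtd.presets` study configuration chosen for CPU-scale
runs: d_model 64, 2 layers, 4 heads, FFN 128, generator width 1/4, max
length 96, masking ratio 0.5, λ = 50, lr 5·10⁻⁴, batch 32, 60 epochs, 6-fold
enumeration; 200 training positives, 30 held-out positives and 30 negatives
scored. One training takes a few minutes on one CPU core. The discriminator
must reach a *sharply fitted* regime for the score to separate classes —
dropout stays at 0 (regularization works against the method; performance
degrades as dropout rises) and under-trained models produce mid-range
probabilities that never cross the token threshold.

## Masking-ratio behavior

Mid-range masking (0.5) robustly outperforms very high masking (0.95), where
the discriminator sees almost no clean context. Very *low* masking (0.05) on
this synthetic bed does **not** degrade: the grammar is clean enough that the
model still learns it from sparse corruptions, and the matched token
threshold (= 0.05) makes inference maximally sensitive. The low-masking
failure reported for curated drug data is a learning failure on harder, more
heterogeneous distributions; the acceptance suite records this divergence
honestly rather than hiding it.

## Numerical and edge-case choices

* Masked positions are all replaced by `<mask>` (no BERT-style 80/10/10
  mixing) before generator sampling; generator filling is temperature-1
  sampling from a dedicated seeded stream.
* Exactly `round(m · n_maskable)` non-special positions are masked per
  sequence, uniformly without replacement.
* Sequences longer than `max_len` are right-truncated with a warning.
* Down-sampling and split rounding use floor; splits are bit-reproducible
  per seed.
* Attention rows are softmax-normalized to 1 within 1e-6; padding is masked
  with −10⁹ additive bias.
* Checkpoints are single `.npz` archives embedding config, vocabulary and a
  vocabulary hash that is validated on load.
* Tokenization covers any character (unknown characters become single-char
  tokens mapping to `<unk>`), so the join round-trip identity holds on all
  inputs; unbalanced brackets fail with a position.
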