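# Methods

## Problem and model

`tcrmil` classifies a T-cell-receptor (TCR) repertoire — the collection of
CDR3β amino-acid sequences observed in one blood sample, each with a clonal
abundance — as reflecting a cancer-associated or healthy immune status.  A
sample is treated as a multiple-instance-learning (MIL) *bag*: the label is
known only at the sample level, while the individual sequences (*instances*)
are unlabelled.

The pipeline has four stages.

**1. Preprocessing** (`repertoire_io`).  Clone tables (MiXCR-style TSV) are
filtered: a CDR3 is kept only if (i) its V-gene locus is resolved, (ii) it
contains none of `X`, `*`, `_`, (iii) it starts with cysteine and ends with
phenylalanine, and (iv) its length is 10–24 residues.  Each rejection is
attributed to the first failing criterion in that order, so the filter
report reads as a per-step survival table.  Survivors are ranked by clone
fraction (clone count when no fraction is present) and the top *k* = 100
form the bag; ties break by lexicographic CDR3 then input order so bags are
permutation-stable.  Bags with fewer than *k* survivors are zero-padded with
masked slots (default) or cyclically resampled.

**2. Embedding** (`embedding`).  Each CDR3 becomes an L×D matrix of
per-residue vectors.  Three backends share one interface:

* `pretrained_plm` — adapter for an external pretrained protein language
  model with the BERT-base contract (12 layers, 12 heads, hidden 768,
  per-head key width d_k = 64).  The checkpoint is optional; without it the
  adapter raises and points at `mini_encoder`, so nothing in the package
  requires a download.
* `mini_encoder` — a seeded randomly initialised transformer encoder
  (default D = 32, 2 layers, 4 heads, sinusoidal positions) built from the
  scaled dot-product attention primitive
  `softmax(QKᵀ/√d_k)V`.  It is not trained; residual connections and layer
  normalisation keep token identity linearly recoverable, which is all the
  downstream convolutional scorer needs.  It exists so the full pipeline,
  including the attention arithmetic, runs deterministically on CPU.
* `physicochemical` — per-residue lookup in a user-supplied 20×P property
  table.  The package ships only a clearly labelled synthetic placeholder
  table (`example_property_table`); there is no silent default.

Embedded instances are zero-padded to Lmax = 24 rows (the maximum
admissible CDR3 length) and stacked into k×Lmax×D tensors (float32).

**3. The CME predictor** (`cme_model`).  Per instance, valid convolutions
with kernel sizes 2/3/4 (3/2/1 filters, F = 6 total) slide over the
*un-padded* span at stride 1 — a length-10 sequence yields 9/8/7 positions —
followed by a monotone activation (sigmoid for the binary model, ReLU for
the multi-class variant) and 1-max pooling.  Because the activation is
monotone, pooling is applied to pre-activations (max-then-activate ==
activate-then-max), which keeps the backward pass a single scatter.
A linear layer with sigmoid turns the pooled 6-vector into a per-sequence
cancer probability ŷᵢ; dropout (rate 0.40) acts on the pooled vector during
training only.  The bag's k ordered probabilities (masked slots contribute
exactly 0) are aggregated by m = 5 parallel linear heads; the head outputs
are averaged and squashed: Ŷ = σ((1/m)Σⱼ(w′ⱼ·ŷ + b′ⱼ)).  A sample with
Ŷ > 0.5 is called cancer; the *health score* is 1 − Ŷ, with values below
0.5 flagged.  Config switches expose the single-head arm (m = 1) and the
mean-pooling baseline (unweighted mean of ŷ, no learned aggregation).

The multi-class variant shares the architecture but uses ReLU activations,
per-class un-normalised scores and an argmax decision (ties to the lowest
class index); training uses softmax cross-entropy.

**4. Training** (`training`).  Adam (lr 0.001, weight decay 0.001), batches
of 100 bags, at most 1000 epochs.  The loss is the ε-clamped (1e-7) binary
cross-entropy of the bag score **plus** the mean per-sequence cross-entropy
in which each instance inherits its bag's label
(`aux_sequence_loss_weight`, default 1.0).  Both levels of supervision are
part of the published training objective; we found the joint form necessary
in practice — the bag term alone spreads its gradient over k = 100
instances and two sigmoids, too diluted for the motif filters to leave
their random initialisation within any realistic epoch budget.  The
aggregation heads are initialised near the uniform average (1/k with small
seeded noise) for the same reason: a zero-mean random init feeds the
sequence path sign-incoherent gradients, because informative instances sit
at arbitrary abundance ranks.

Early stopping monitors the validation value of the full objective with
patience 40; model selection is decoupled and returns the parameters of the
epoch with the best validation AUC (validation accuracy for the multi-class
task, AUC being a binary notion).  `train_with_restarts` repeats the whole
procedure from fresh seeded initialisations and keeps the restart with the
best validation metric (ties to the lowest seed); the published protocol
used 50 restarts, the package default is 1.

Everything is deterministic given the seed: per-epoch shuffling and dropout
use generators derived from (seed, epoch), and two runs with identical
inputs produce bit-identical parameters.

## Evaluation (`evaluation`)

Confusion counts use prediction = score > threshold (default 0.5).
Accuracy, sensitivity, specificity, precision and F1 follow the standard
formulas exactly; zero-denominator metrics are reported as NaN with a
warning rather than silently zeroed.  ROC and PRC curves and areas come
from scikit-learn (threshold sweep with tied scores grouped; PRC area by
step interpolation); tests cross-check the ROC area against an independent
pairwise-concordance oracle.  Spearman correlation and the Mann–Whitney U
test (tie-corrected, two-sided) are delegated to scipy; significance stars
map ns / * / ** / *** at 0.05 / 0.01 / 0.001.

## Synthetic cohorts (`synthetic_data`)

The generator reproduces the statistics the method relies on, not V(D)J
recombination biology:

* lengths: rounded Gaussian (mean 14.5, sd 2.0 — placing 12–16-mers as the
  most common) truncated to [10, 24];
* composition: C…F anchors with uniform interior residues by default (a
  custom background table can be supplied);
* abundances: Zipf law over ranks (exponent 1.2), normalised to fractions;
* signal: short 3–4-mer motifs planted at uniform interior positions in a
  fraction f = 0.3 of case-bag instances and f0 = 0.02 of control
  instances;
* clonal expansion: motif-bearing clones are favoured for high abundance
  ranks via a Plackett–Luce draw with log-odds `expansion_bias` = 1.5,
  emulating antigen-driven expansion of tumour-reactive clones.  This is
  what gives a *learned* bag aggregation something the uniform mean cannot
  exploit; with the bias at 0, motif presence is independent of rank and
  uniform pooling is already near-optimal.

Every generated sequence passes the default quality filters by
construction, and ground-truth per-instance motif flags are carried through
to the bag slots for diagnostics.  What the generator does **not** emulate:
germline V/D/J segment structure, nucleotide-level convergent recombination,
realistic amino-acid backgrounds, shared public clones between samples, or
batch effects.  A passing end-to-end test therefore shows the architecture
and optimiser can recover a planted sequence signal under realistic length
and abundance statistics — not that the published real-data accuracies are
reproduced.

## Problem sizes used by the test suite

The packaged checks run the full method at desk scale: end-to-end recovery
uses the default generator (100 bags per class, 120 clones per sample,
k = 100, mini-encoder D = 32, one restart) with the default training
protocol capped at 300 epochs (model selection lands well inside that cap);
the matched null check regenerates the same cohort with f = f0.  Held-out
AUCs are measured on a second freshly generated cohort of the same size and
distribution rather than on the 40-bag test split: under the null the split
estimate has a standard deviation near 0.09, which would make any tight
interval around 0.5 a coin flip, while the 200-bag fresh cohort brings it
to about 0.04.

The aggregation ablation (mean pooling vs single learned head vs 5-head
ensemble) runs on one default-signal cohort of 100 bags per class with
k = 50, 60 clones per sample and a 24-wide encoder, five seeds, batch size
50 and a 200-epoch cap, each arm trained with best-of-2 restarts selected
by validation AUC — the published restart-and-select protocol at reduced
count, applied identically to every arm.  Median held-out AUCs are compared
with a 0.05 sampling tolerance.  Single-restart training leaves the learned
aggregation arms high-variance (they occasionally collapse while the
parameter-free mean cannot); restart selection is what stabilises them.  At
this scale the three arms finish within tolerance of one another, with the
uniform mean marginally ahead — the learned aggregation's advantage on real
repertoires is not reproduced by this generator, whose planted instances
are individually informative enough that uniform averaging is already near
optimal.

## Numerical choices

* Probability clamp 1e-7 in all cross-entropies; sigmoids computed in the
  numerically stable split form.
* Max-pooling ties resolve to the first (leftmost) position via argmax.
* Multi-class argmax ties resolve to the lowest class index.
* Cohort splitting uses largest-remainder apportionment per class
  (stratified by default), so 10 samples at 6:2:2 give exactly 6/2/2.
* Weight decay is added to the gradient (the convention of the reference
  deep-learning stack), not decoupled.
* Embedding tensors are float32; parameters and optimiser state float64.

## Known limitations

* The pretrained-language-model path is an adapter contract; no checkpoint
  ships with the package, so its 768-wide output is exercised only through
  the declared configuration and a stub in tests.
* The mini encoder is untrained; its embeddings carry no transfer-learned
  biology, so absolute accuracies on synthetic data say nothing about the
  published real-data numbers.
* Single-restart training is noticeably seed-dependent (the published
  protocol's 50 restarts exist for a reason); the best-of-restarts API is
  provided but not the default.
* The Mann–Whitney implementation uses the normal approximation inherited
  from scipy for moderate sample sizes.
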