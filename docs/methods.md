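# Methods

## The classification model

`cathsf` treats CATH superfamily assignment as flat multiclass
classification over the superfamilies present in the training set.  A
domain is summarized by mean-pooled per-residue embeddings in one or two
channels — amino-acid sequence (AA) and structural-alphabet sequence
(3Di) — and a feed-forward network maps the pooled vector to class
probabilities.  The network body is `n_layer_blocks` repetitions of
dense → LeakyReLU → batch normalization → dropout, then a dense softmax
head.  The model is closed-set by construction: it cannot name a
superfamily absent from its label space, only decline to answer via the
confidence threshold.

Assumptions worth stating explicitly:

* Mean pooling discards residue order and length; two domains with
  similar per-residue embedding distributions are near-identical inputs.
* The AA-then-3Di concatenation order is fixed; models and embedding
  stores are only interchangeable when channel, embedder id, and
  dimension all agree (the store enforces this).
* The pLDDT filter presumes B-factors of predicted models are
  confidences.  Calling `extract_mean_plddt` on an experimental
  structure raises rather than averaging thermal B-factors — mixing the
  two semantics would silently corrupt the filter.

## Structure processing

Domains are substrings of deposited chains, so the 3Di path aligns the
domain sequence to the chain read from PDB (Cα trace, first altloc,
HETATM skipped) and trims to the aligned span.  Alignment is local with
affine gaps — match +1, mismatch −1, open −5, extend −0.5 — because
local mode leaves chain overhangs unpenalized.  A mapping is accepted at
coverage ≥ 0.9 and identity = 1.0 by default; strict identity prevents
silently pairing a domain with a homologous-but-wrong chain, and a
failed mapping marks the domain structure-unavailable rather than
aborting a run.  The acceptance rule is a package decision (configurable
per call); upstream pipelines report only that some structures were
unusable, not their criterion.

The shipped `MockGeometricEncoder` maps each residue to a letter by the
distance to its nearest non-adjacent Cα, binned at 0.5 Å from a 3.0 Å
floor into 20 states.  It imitates the *shape* of a tertiary-interaction
alphabet — deterministic, one letter per residue, sensitive to spatial
context — and deliberately makes no attempt to reproduce Foldseek's
numeric 3Di states, which remain behind the external-encoder adapter.

## Dataset filters

Order: structure availability → pLDDT → support, with label-space
harmonization after each stage.  Structure loss shrinks class supports
before the support filter counts them, which is the order in which the
two effects interact in real data.  Boundary semantics: pLDDT removes
train domains strictly below the threshold (24.0 keeps a 24.0 domain);
support removes superfamilies at-or-below (10 removes a support-10
class); 0 disables either filter.  The pLDDT criterion touches training
domains only — validation and test shrink solely by whole-superfamily
removal.  Every stage logs removal counts per split in the bundle's
provenance, so input counts always reconcile with survivors plus
removals, and both filters are monotone: survivors at a stricter
threshold are a subset of survivors at a looser one.

## Training and inference

The published architecture comes without a training protocol, so the
loop here is a conventional one, fully exposed on `ClassifierConfig`:
categorical cross-entropy, Adam, batch size 256, at most 200 epochs,
early stopping on validation loss with patience 10 and best-weight
restore.  The default learning rate is 1e-4; the desk-scale runs in the
test suite and acceptance script pass 1e-3 with 25–60 epochs, which
converges on their small, well-separated problems in seconds.  Weights
are He-initialized from the config seed; batch-norm running statistics
use 0.9 momentum and ε = 1e-5; dropout is inverted.  Inference uses
running statistics with dropout off, so predictions are deterministic;
softmax rows sum to 1 within 1e-6 and argmax ties break to the lowest
class index.  Class indices are the lexicographic order of superfamily
codes.  Optional switches (off by default, since the source work
mentions neither): per-feature standardization fitted on train only, and
inverse-frequency class weighting.

The implementation is plain numpy, including backpropagation through
the batch-norm layers (verified against central finite differences in
the test suite).  At desk scale a full training run is seconds on one
CPU, and a framework-free forward/backward keeps runs bit-reproducible
for a fixed seed and thread count.

## Metrics and uncertainty

Macro F1 is the headline metric: under heavy class imbalance it weighs
a rare superfamily equally with a huge one.  It averages per-class F1
over classes present in the truth or the predictions of the evaluated
sample; a class the model never predicts correctly contributes 0, while
label-space classes absent from the sample altogether do not dilute the
mean (so a perfect prediction always scores 1).  Balanced accuracy
averages recall over classes present in the truth; MCC uses the
multiclass confusion-matrix form.  All four are computed from the
confusion matrix in vectorized numpy — one code path serves point
estimates and bootstrap replicates, keeping a 1000-replicate bootstrap
sub-second — and the implementation is cross-checked against
scikit-learn in the tests.

Confidence intervals resample (truth, prediction) pairs with
replacement at full test-set size, `n_boot` = 1000 times, and report
half-width = z × replicate standard deviation with z = 1.96.  The model
is not retrained per replicate; the interval quantifies test-sampling
noise around fixed predictions.  Single-sample test sets and
`n_boot` < 2 are rejected explicitly.

The grid runner evaluates the cartesian product over layer blocks,
layer size, dropout, input type, and both filter thresholds, appending
one CSV row per combination as it completes (a crash loses at most one
row); a failing combination is recorded with its reason and the run
continues.

## Synthetic fixtures: what they do and do not show

`gen_structure_set` writes helix-like Cα traces (≈3.8 Å spacing, seeded
jitter) whose B-factor column realizes a drawn mean pLDDT exactly, with
a configurable fraction of domains withheld to plant retrieval
failures.  `gen_embedding_dataset` draws one class center per channel
on a hypersphere of radius `separation` (default 6, in units of the
noise sd, default 1 — far enough that between-class overlap is
negligible at the default dimensions), adds isotropic Gaussian noise,
and can collapse chosen class pairs onto a shared center in one channel
only.  Channel informativeness is therefore controlled exactly: a
channel's Bayes accuracy follows from its collapse structure (at most
one class per collapsed group can be predicted correctly), and the
generator reports it.  Per-class training supports may follow a power
law (default exponent 1.2 from a 60-domain maximum) to emulate the
heavy imbalance of real superfamily data, including classes below
support 10.

These fixtures exercise bookkeeping, optimization, calibration, and the
qualitative channel-complementarity effect.  They do not emulate real
pLM embedding geometry — anisotropic, non-Gaussian, with correlated
channels — nor realistic protein folds, sequence–structure coupling, or
the long-tailed label space of the full corpus.  Passing tests
demonstrate that the machinery is correct and that the pipeline
recovers known structure under its stated conditions; they say nothing
about absolute accuracy on real embeddings, which requires the full
dataset and GPU-scale embedding.

## Problem sizes

The test suite and acceptance script run, per invocation: a 50-class
recovery problem (60/10/10 domains per class, 16+16 dims, 2×256
network), a 20-class channel-comparison grid (three models at 2×128),
a ~1160-domain filter-cascade grid (8 cascades), 200 bootstrap
calibration sets of n = 1000 at 1000 replicates each, and a 20-domain
structure round trip.  These sizes were chosen so the whole suite
completes in about a minute on a single CPU while keeping every check
statistically comfortable.

## Known limitations

* Closed-set: no "other" class; the 0.9 confidence rejection is a
  pragmatic guard, not open-set recognition.
* Real encoders/embedders are adapters only; nothing here reproduces
  Foldseek 3Di states or any specific pLM numerically.
* Multi-model PDB files collapse to the first model; mmCIF is out of
  scope.
* The Bayes-accuracy figures reported by the generator ignore residual
  Gaussian overlap between distinct centers; they are tight only when
  `separation`/`noise_sd` is large, as in the defaults.
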