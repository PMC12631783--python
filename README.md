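# cathsf

Assigning a protein domain to its CATH homologous superfamily (SF) from
sequence alone is the workhorse of remote-homology annotation: with more
than 1700 populated superfamilies and pairwise sequence identities below
20% between training and query domains, profile methods start to miss
what structure still sees.  `cathsf` implements a structure-aware
classification pipeline for this problem, aimed at structural
bioinformaticians who want to train, filter, and evaluate such
classifiers — or run confidence-thresholded inference with an existing
model — without GPU infrastructure in the loop.

## The method

Each domain is represented by pooled protein-language-model (pLM)
embeddings in up to two channels:

* **AA** — the amino-acid sequence is embedded per residue and
  mean-pooled: `v_AA = (1/L) Σ_i e(s_i)` for an L-residue domain;
* **3Di** — the domain's 3D structure is first reduced to a 20-letter
  structural-alphabet string (one letter per residue, describing the
  geometry of each residue's closest tertiary contact), which is embedded
  and pooled the same way.

To build the 3Di channel, the domain sequence is aligned to the chain of
its PDB file (local alignment, affine gaps), the structure is trimmed to
the aligned span, and the trimmed Cα model is handed to a pluggable
structural-alphabet encoder.  Predicted models carry per-residue pLDDT
(0–100) in the B-factor column; the mean over a domain's residues drives
a quality filter.

The classifier input is `v_AA`, `v_3Di`, or their concatenation
`[v_AA ; v_3Di]`.  The network is a feed-forward stack of *layer blocks*

    dense(h) → LeakyReLU → batch-norm → dropout(p)

repeated `B` times, followed by a softmax output over the label space
(defaults `B = 2`, `h = 2048`, `p = 0.3` on AA+3Di input).  Before
training, an optional filter cascade shapes the dataset: domains without
a usable structure are dropped when 3Di is involved; training domains
with mean pLDDT under a threshold are dropped; superfamilies with
training support ≤ a threshold are dropped; and the label space is
re-harmonized after every stage so validation/test never contain a class
the training set lost.

Evaluation reports macro F1 (the headline metric under heavy class
imbalance), accuracy, balanced accuracy, and multiclass MCC, each with a
95% confidence interval from a 1000-replicate test-set bootstrap
(half-width = 1.96 × the replicate standard deviation).  At inference, a
prediction whose top softmax probability falls below a threshold
(default 0.9) is returned as rejected rather than forced into a class —
a practical guard against domains from superfamilies the model never
saw.

Real pLMs (ProstT5, ProtT5, ESM2, Ankh, TM-Vec, …) and the Foldseek 3Di
encoder plug in through adapter contracts; the package ships
deterministic mock embedders/encoders and a synthetic-fixture generator,
so the entire pipeline is testable at desk scale.

## Worked example

```python
import tempfile
from cathsf import (SyntheticSpec, gen_embedding_dataset, ClassifierConfig,
                    build_classifier, train_classifier, predict_proba,
                    predict_with_rejection, bootstrap_ci)
from cathsf.evaluation import assemble_design

work = tempfile.mkdtemp()
spec = SyntheticSpec(seed=0, n_classes=25, train_support=30,
                     n_val_per_class=5, n_test_per_class=5,
                     confusion_aa=((0, 1),))   # a pair AA alone cannot separate
bundle, store, info = gen_embedding_dataset(spec, f"{work}/embeddings.h5")
print("label space:", len(bundle.label_space), "superfamilies;",
      "splits:", bundle.counts())
print("Bayes accuracy per input type:", info["bayes_accuracy"])

design = assemble_design(bundle, store, "AA+3Di")
store.close()
config = ClassifierConfig(n_layer_blocks=2, layer_size=128, dropout_rate=0.3,
                          input_type="AA+3Di", epochs=60,
                          learning_rate=1e-3, seed=0)
model = build_classifier(config, design["train"][0].shape[1],
                         label_space=bundle.label_space)
train_classifier(model, *design["train"], *design["val"])

x_test, y_test = design["test"]
y_hat = predict_proba(model, x_test).argmax(axis=1)
report = bootstrap_ci(y_test, y_hat, model.n_classes, n_boot=1000, seed=0)
print(f"macro F1 {report.f1_macro:.3f} ± {report.ci_halfwidth['f1_macro']:.3f}")
print(f"accuracy {report.accuracy:.3f} ± {report.ci_halfwidth['accuracy']:.3f}")

calls = predict_with_rejection(model, x_test[:3], confidence_threshold=0.9,
                               domain_ids=[r.domain_id for r in bundle.test[:3]])
for c in calls:
    print(c.domain_id, c.label, f"{c.confidence:.3f}",
          "REJECTED" if c.rejected else "")
```

prints

```
label space: 25 superfamilies; splits: {'train': 750, 'val': 125, 'test': 125}
Bayes accuracy per input type: {'AA': 0.96, '3Di': 1.0, 'AA+3Di': 1.0}
macro F1 1.000 ± 0.000
accuracy 1.000 ± 0.000
C000_035 1.10.1.10 0.972
C000_036 1.10.1.10 0.990
C000_037 1.10.1.10 0.994
```

The generator collapsed superfamilies 0 and 1 onto one AA-channel
center, so the AA channel alone tops out at Bayes accuracy 0.96 while
the 3Di channel — and the concatenation the model was trained on —
separates everything; the trained classifier reaches the concatenated
channels' Bayes rate, and its first three test calls clear the 0.9
confidence threshold.

The same flow is available from the shell via the `cathsf` CLI
(`make-fixtures`, `embed`, `filter`, `train`, `predict`, `evaluate`,
`grid`); `cathsf predict --tsv-out calls.tsv` writes one
`domain_id / predicted_sf / confidence / rejected` row per domain.

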