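# locboost

Multi-label prediction of protein subcellular localization by combining a
1D convolutional feature extractor with second-order gradient-boosted
decision trees.

A protein may reside in several compartments at once (nucleus and
cytoplasm, say), so localization is a multi-label, multi-class problem.
`locboost` implements a hybrid predictor:

1. **Encoding.** Each protein is represented as an *L* × 1 similarity
   profile against the *L* training proteins — cosine similarity of
   overlapping k-mer count vectors by default (k = 3), or cosine
   similarity of column-averaged PSSM rows when PSI-BLAST profiles are
   available, optionally blended with a precomputed protein–protein
   interaction score matrix as `α·seq + (1−α)·ppi`.
2. **Feature extraction.** A 1D CNN (conv → ReLU → max-pool blocks, then
   fully-connected ReLU layers) is trained on these profiles with the
   multi-label binary cross-entropy objective over sigmoid activations,

   L(Θ) = −(1/n) Σᵢ Σⱼ [ yᵢⱼ log σ(fᵢⱼ) + (1−yᵢⱼ) log(1−σ(fᵢⱼ)) ].

   The classifier head is then discarded; the post-ReLU activations of
   the last hidden layer become the learned feature representation.
3. **Classification.** One gradient-boosted tree ensemble per location
   (binary relevance), written from scratch with the second-order
   objective: with G and H the per-leaf sums of the first and second
   derivatives of the logistic loss, the optimal leaf weight is
   w\* = −G/(H+λ) and a split's gain is
   ½[G²_L/(H_L+λ) + G²_R/(H_R+λ) − G²_P/(H_P+λ)] − γ.
   Trees are grown by exact greedy enumeration of every feature and
   every midpoint between consecutive distinct values.
4. **Decision.** Per-location probabilities ≥ 0.5 form the predicted
   label set; an empty set falls back to the single argmax location.

Evaluation uses the field's multi-label measures: per-protein Jaccard
accuracy TP/(TP+FP+FN) averaged over proteins (ACC-mean), and
per-location F1 — the harmonic mean of precision and recall, each
averaged over the proteins predicted at / truly at the location
(F1-mean).

The entire stack (CNN included) is plain numpy and bit-deterministic
under a fixed seed. A synthetic-data generator plants location-specific
sequence motifs so the whole pipeline can be exercised and benchmarked
without any external datasets or services.

## Worked example

```python
from locboost import SynthConfig
from locboost.pipeline import run_synth_benchmark

config = SynthConfig(n_train=300, n_test=100, n_locations=4,
                     motif_len=5, motif_insert_prob=0.95,
                     multilabel_prob=0.3, seed=7)
result = run_synth_benchmark(config)
for variant in ("pipeline", "cnn_only"):
    r = result[variant]
    print(f"{variant:>9}: ACC-mean {r.acc_mean:.4f}  F1-mean {r.f1_mean:.4f}")
```

prints

```
 pipeline: ACC-mean 0.9450  F1-mean 0.9583
 cnn_only: ACC-mean 0.9550  F1-mean 0.9658
```

Four locations, each tagged by a planted 5-residue motif carried by 95%
of its member proteins; 30% of proteins carry a second label.  Both the
full pipeline (CNN features + boosted trees) and the CNN-only baseline
(its own sigmoid head, thresholded) recover the planted structure almost
perfectly on the 100 held-out proteins — ACC-mean is the mean Jaccard
overlap between predicted and true label sets, F1-mean the unweighted
mean per-location F1.

The same workflow is available from the shell:

```sh
locboost synth --out-dir data --n-train 300 --n-test 100 --seed 7
locboost train --train-fasta data/train.fasta --train-labels data/train.tsv \
               --bundle model.joblib --seed 7
locboost predict --bundle model.joblib --fasta data/test.fasta --out preds.tsv
locboost eval --predictions preds.tsv --truth data/test.tsv --out report.tsv
```

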