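# peploc

Subcellular localization prediction for **partial (EST-derived) peptide
sequences**. Full-length-protein predictors perform poorly on EST-peptides,
which are short (~200 residues) and usually missing the N-terminal targeting
signal; `peploc` attacks the problem with RBF-kernel SVMs over sequence
features that do not depend on having the whole protein.

## What it implements

- **Feature extraction** (`peploc.features`) — 41 fixed representations:
  - 1 physicochemical summary (per-index average over the sequence, from an
    AAindex1-format table; the packaged synthetic snapshot has 494 indices),
  - k-mer composition of the plain 20-letter alphabet (orders 1–6),
  - k-mer composition under two reduced alphabets (orders 1–8 each):
    *group C* — 8 chemical groups, *group D* — 10 structural groups,
  - gapped ordered-pair composition (gap lengths 1–6, all three alphabets).
  All composition vectors are sparse maps; dimensions up to 20⁶ are handled
  without dense allocation. A tetra-peptide motif audit summarizes how 4-mers
  distribute across compartment classes.
- **Classification** (`peploc.model`) — one-vs-one RBF-SVM with probability
  outputs (scikit-learn/libsvm backend), per-dimension [0, 1] scaling fitted
  on training data only, deterministic fold construction, grid search for
  (C, γ), and a nested 10-fold cross-validation protocol: inner folds select
  hyperparameters, outer folds estimate performance.
- **Integration** (`peploc.integration`) — five prediction schemes: single
  best feature, attribute concatenation (all 41 or top-3), and two-layer
  probability stacking (all 41 or top-3). Stacking concatenates the 9-class
  probability outputs of all first-layer models into a meta vector
  (41 × 9 = 369 dimensions) feeding a second-layer SVM. The top-3 members
  are `ungrouped_k4`, `groupC_k6`, `groupD_k7`.
- **Evaluation** (`peploc.evaluation`) — overall accuracy plus per-class
  SN/SP/PPV/MCC, aggregated over folds as mean (sample SD). Zero
  denominators report 0 and are flagged undefined.
- **Dataset expansion** (`peploc.expansion`) — fragments full-length
  proteins into EST-like pieces (1/2/3 fragments for lengths <200 /
  200–400 / >400; fragment lengths 140–260; N-terminal fragments anchored
  within 80 residues of the first methionine; C-terminal fragments end at
  the last residue) and removes redundancy by greedy longest-first
  clustering at 60 % local-alignment identity.
- **Synthetic data** (`peploc.synthetic_data`) — labeled EST-peptide-like
  datasets with a tunable compositional class signal and optional planted
  tetra-peptide motifs, plus a generator for valid AAindex1 fixture files.
- **CLI** (`peploc.cli`) — `simulate`, `expand`, `extract-features`,
  `train`, `predict`, `evaluate`, `audit`.

## CLI quick start

```sh
# make a toy labeled dataset
peploc simulate --out-fasta data.fa --out-labels labels.tsv \
    --classes chl,cyt,mit --n-per-class 20 --signal 1.0 --seed 1

# train a single-feature scheme (config is YAML)
cat > config.yaml <<EOF
scheme: single_feature          # or concat_attributes / stacked_predictions
members: [ungrouped_k4]
grid: {log2_C: [-1, 3, 7], log2_gamma: [-7, -3, 1]}
folds: {outer: 10, inner: 10}
EOF
peploc train --fasta data.fa --labels labels.tsv --config config.yaml \
    --out model.joblib --seed 1

# predict (add --translate to accept nucleotide ESTs via the heuristic
# six-frame translator; --aaindex FILE if the scheme uses the aaindex feature)
peploc predict --fasta query.fa --model model.joblib --out predictions.tsv

# nested cross-validated evaluation
peploc evaluate --fasta data.fa --labels labels.tsv --config config.yaml \
    --out-tsv report.tsv --out-json report.json --seed 1
```

Prediction output is a TSV with the argmax class and the probability for
every class. Inputs longer than 400 residues trigger a warning — the method
is designed for partial sequences, not full-length proteins.

## Layout

```
src/peploc/
  sequence_io.py    FASTA I/O, cleaning, reduced alphabets, frame translation
  features.py       feature families, registry, tetra-peptide audit
  expansion.py      protein fragmentation + identity clustering
  model.py          SVM training, folds, grid search, nested evaluation
  integration.py    concatenation and two-layer stacking schemes
  evaluation.py     SN/SP/PPV/MCC/accuracy, fold aggregation, report writers
  synthetic_data.py dataset and AAindex fixture generators
  cli.py            command-line interface
tests/              unit, property and acceptance tests
scripts/acceptance.py
```
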