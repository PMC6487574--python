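# origincall

Tissue-of-origin classification from whole-transcriptome expression.

`origincall` implements a five-member neural-network ensemble that calls a
tumor's primary site from RNA-seq gene expression (log2(RPKM + 1)). Each
member sees the same training cohort through a different per-gene linear
rescaling (standardize, min–max, max-abs, robust, and a second standardized
member augmented with SMOTE oversampling of rare classes), so the members
make partially independent errors. Per sample, each member votes for its
top-probability class; the call is the modal vote, the confidence score is
the mean winning-class probability over the members that voted for it, and
calls whose runner-up class draws two or more votes are flagged as
*split-confidence* — a pattern characteristic of mixed-histology samples.

The package also provides:

- **ANOVA feature selection** — per class-pair F tests with Bonferroni
  correction within each pair; genes ranked by the number of class pairs
  they separate.
- **Connection-weight gene importance** — per class, the sum over all
  hidden paths of the products of network weights (Olden's method), with
  the member's per-gene affine rescaling composed into the first layer, so
  scores are comparable across members.
- **Evaluation** — one-vs-rest TP/TN/FP/FN per class, precision / recall /
  F1 / FPR with macro (unweighted) averaging, confident-subset accuracy,
  a misprediction taxonomy (biopsy-site match, organ-system match, other),
  and association tests (tumor content × correctness, confidence ×
  correctness, class size × accuracy).
- **A linear comparator** — multinomial logistic regression on an
  ANOVA-selected gene subset, for paired baseline comparisons.
- **A synthetic-cohort generator** — log-normal expression with planted
  per-class marker genes, optional paired adjacent-normal classes,
  mixed-histology samples, and tumor-content dilution, with ground truth
  returned for every cohort.

## Worked example

Generate a synthetic cohort (8 tumor classes × 60 samples, 400 genes, 10
planted marker genes per class), train the ensemble, and inspect calls,
held-out performance, and gene importance:

```python
from origincall import (
    SyntheticSpec, generate_cohort, stratified_split,
    train_ensemble, predict_cohort, evaluation_report, ensemble_importance,
)

cohort, truth = generate_cohort(SyntheticSpec(seed=1))
train, test = stratified_split(cohort, 0.8, seed=1)

model = train_ensemble(train, random_state=1,
                       max_epochs=200, early_stopping_fraction=0.0)
preds = predict_cohort(model, test.matrix)
print(preds[["sample_id", "call", "confidence", "vote_count", "split"]].head())

labels = {m.sample_id: m.class_label for m in test.metadata}
report = evaluation_report([labels[s] for s in preds["sample_id"]], preds["call"])
mean, sd = report.macro["F1"]
print(f"test macro-F1: {mean:.2f} (SD {sd:.2f})")

top = ensemble_importance(model, "C1", top_n=5)
print(top.to_string(index=False))
print("planted C1 markers:", truth.marker_sets["C1"][:5], "...")
```

Output:

```
  sample_id call  confidence  vote_count  split
0    S00010   C1    0.967284           5  False
1    S00036   C1    0.992649           5  False
2    S00005   C1    0.982655           5  False
3    S00008   C1    0.938834           5  False
4    S00032   C1    0.989582           5  False
test macro-F1: 1.00 (SD 0.00)
class  rank gene_id    score
   C1     1   G0008 0.842542
   C1     2   G0002 0.840439
   C1     3   G0009 0.764636
   C1     4   G0000 0.705941
   C1     5   G0004 0.704802
planted C1 markers: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004'] ...
```

All five top-importance genes for class `C1` are planted `C1` markers.

## Command line

Every stage is also a subcommand of the `origincall` CLI:

```bash
origincall simulate --seed 1 --out-dir cohort/          # expression + labels + truth
origincall select-features --expr cohort/expression.tsv --labels cohort/labels.tsv \
    --k 100 --out genes.tsv
origincall train   --expr ... --labels ... --out-dir model/
origincall predict --model model/ --expr ... --out predictions.tsv
origincall importance --model model/ --all --top-n 20 --out importance.tsv
origincall evaluate --truth ... --predictions predictions.tsv --out-prefix eval
origincall baseline --expr ... --labels ... --test-expr ... --out baseline.tsv
```

`origincall run --config run.json --out-dir out/` executes the full
pipeline (split → train → predict → evaluate → importance) and writes the
serialized model, prediction and evaluation tables, an importance table, a
log, and a manifest with input digests. The config JSON requires
`expression` and `labels` paths; optional keys include `seed`,
`train_fraction`, `confidence_threshold`, `organ_map`, `smote`
(`{"strategy": ..., "k": ..., "targets": ...}`), and `ensemble`
(hyperparameters forwarded to the ensemble, e.g.
`{"hidden_layer_sizes": [128], "max_epochs": 200}`).

## Bundled worked-example data

`origincall.evaluate.load_metastatic_worked_example()` returns a published
per-class one-vs-rest count table for a 201-sample metastatic validation
cohort (23 class rows plus totals, with misprediction-category counts).
The evaluation module reproduces the printed per-class precision / recall /
F1 from the raw counts for every non-grouped row, and the cohort totals as
unweighted means of the per-row values (precision 0.86, recall 0.76,
F1 0.79, FPR 0.005). See `docs/methods.md` for caveats about the grouped
rows.

## Documentation

`docs/methods.md` describes the model, its parameters, the synthetic-data
design and what it can and cannot demonstrate, numerical choices, and
known limitations.
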