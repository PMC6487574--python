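# Methods

## Model

The classifier is an ensemble of five multilayer perceptrons trained on
log2(RPKM + 1) whole-transcriptome expression. The members differ only in
the per-gene linear transform fitted on the training data and, for one
member, in rare-class augmentation:

| member | transform | augmentation |
|--------|-----------|--------------|
| 0 | standardize (mean 0, population SD 1) | — |
| 1 | min–max to [0, 1] | — |
| 2 | max-abs to [−1, 1] | — |
| 3 | robust (median 0, IQR 1) | — |
| 4 | standardize | SMOTE |

Each member is a scikit-learn `MLPClassifier`: one hidden layer of 128
ReLU units by default, softmax output, Adam optimizer, L2 penalty 1e-4, up
to 200 epochs, optional accuracy-based early stopping on a 10% validation
split. Member *i* is seeded with `random_state + i`, so members differ in
initialization as well as in transform.

### Vote and confidence aggregation

For a sample, each member's *top vote* is its highest-probability class.
The call is the modal top vote; ties break first by the larger
ensemble-mean probability, then lexicographically. The confidence score is
the mean winning-class probability over the members that voted for the
winning class (configurable to average over all members instead). A call
is flagged *split-confidence* when the runner-up class receives at least
`vote_threshold` votes (default 2), indicating the ensemble is divided
between two classes.

### SMOTE

Synthetic minority samples are linear interpolations `x_i + u·(x_nn −
x_i)` with `u ~ Uniform(0, 1)` between a uniformly chosen class sample and
one of its k = 5 nearest same-class neighbors (Euclidean distance in the
member's transformed space; k is capped at class size − 1). Every
synthetic point therefore lies on a segment between two real class
samples. By default, classes below the median class size are raised to the
median; a class of size 1 cannot be interpolated and is duplicated, with a
warning.

### ANOVA gene selection

For every pair of classes, a one-way F test is computed per gene, with
Bonferroni correction *within the pair* across the testable
(non-constant) genes. A gene's score is the number of class pairs for
which it is significant at the corrected threshold (alpha 0.05); the top-k
genes by score are selected (default k = 3000), with ties broken by the
smallest raw p value and then lexicographically by gene id. Pairs in
which a class has fewer than 2 samples are skipped with a warning.

### Gene importance

Per class and member, a gene's score is the sum over all hidden paths of
the products of connection weights from that input to the class's output
unit (Olden's connection-weight method), computed after composing the
member's per-gene scale into the first layer so that scores are
comparable across differently rescaled members. Ensemble scores rescale
each member's vector to unit maximum absolute value, then average; genes
are ranked by absolute score with lexicographic tie-breaks.

### Linear comparator

Multinomial logistic regression (with per-gene standardization) on an
ANOVA-selected gene subset, L2-regularized. It is trained and evaluated on
exactly the same splits as the ensemble for paired comparisons.

## Evaluation conventions

- Counts are one-vs-rest TP/TN/FP/FN per class.
- precision = TP/(TP+FP), recall = TP/(TP+FN), FPR = FP/(FP+TN),
  F1 = harmonic mean. Undefined ratios (zero denominator) are reported as
  0.0 and flagged.
- Macro metrics are unweighted means across classes, with the SD computed
  with one delta degree of freedom.
- Confident-subset accuracy restricts to calls with confidence ≥ 0.80; an
  empty subset is reported as undefined, not zero.
- Mispredictions are categorized with priority: correct diagnosis →
  biopsy-site tissue match → same organ system → other.
- Tables are rounded to 2 decimals (FPR to 3) for display.

### Bundled worked-example table

`data/metastatic_cohort_counts.tsv` transcribes a published per-class
count table for a 201-sample metastatic validation cohort. Two caveats:

- Rows for *grouped* diagnoses (marked `grouped = 1`) do **not** reproduce
  their printed precision/recall/F1 from their own TP/TN/FP/FN counts; the
  printed values presumably reflect pre-grouping bookkeeping not
  recoverable from the table. Reproduction checks are restricted to
  non-grouped rows.
- The cohort "Total" metrics are the unweighted means of the 23 printed
  per-row values (precision 0.86, recall 0.76, F1 0.79, FPR 0.005), not
  metrics of the summed counts. Per-row FPR is printed at 2 decimals; the
  total at 3.

## Synthetic data

Cohorts are drawn from a log-normal model: on the log2 scale each gene is
Normal(base + delta·[gene is a class marker], sd), then mapped to
RPKM = max(2^z − 1, 0). Defaults: 8 balanced classes × 60 samples, 400
genes, 10 disjoint markers per class, delta = 6, base = 3, sd = 1.
Optional paired adjacent-normal classes share the first half of their
tumor class's markers (tissue signal) but not the second half (tumor
signal). Mixed-histology and diluted-tumor-content samples mix class
log-mean vectors, not drawn samples.

**What the synthetic experiments show:** that the implementation learns
planted structure — near-perfect held-out macro-F1 at delta = 6; recovery
of planted markers in the top of the importance ranking; elevated
split-confidence rates on 50/50 class mixtures; confident-subset accuracy
at least the overall accuracy under moderate overlap (delta = 2); and a
SMOTE member whose rare-class recall is at least the matching plain
member's in the majority of seeds when one class has 5 training samples
against 100.

**What they cannot show:** any real-data performance level (the published
held-out and external-cohort accuracies require controlled-access
clinical cohorts), and any advantage of the ensemble *over* the linear
comparator: the generator is homoscedastic Gaussian per class on the log
scale, for which a linear decision boundary is Bayes-optimal, so logistic
regression is already the right model family on these cohorts and the
ensemble can at best match it. Tests therefore assert the ensemble
*matches* the comparator on synthetic data rather than beating it.

## Numerical choices

- Standardization uses the population SD (ddof 0); degenerate scale
  denominators (constant gene for standardize/min–max/robust, all-zero
  gene for max-abs) are replaced by 1 so transforms stay finite.
- Bonferroni correction divides alpha by the number of testable
  (non-constant) genes in the pair, not the full gene count, so adding
  constant genes does not change selections.
- All stochastic steps (simulation, splitting, SMOTE, member
  initialization) are seeded; retraining with the same seed reproduces
  byte-identical member weights (checked by SHA-256 digest).
- Accuracy-based early stopping saturates within ~15 epochs on the
  synthetic cohorts, long before the softmax sharpens; experiments that
  depend on converged members (marker recovery, confidence behavior)
  disable it and train the full 200-epoch budget.

## Limitations

- Only the published count table is bundled; all learning-system claims
  are demonstrated on synthetic cohorts, which are far simpler than real
  transcriptomes (no batch effects, no correlated co-expression modules,
  no heavy tails).
- The per-pair ANOVA aggregation rule (count of significant pairs) and
  the Olden importance aggregation (unit-max rescaled mean) are
  documented choices where the original method description is ambiguous;
  outputs are tagged with the method used.
- Grouped rows of the worked-example table are not reproducible from
  their own counts (see above).
- The MLP backend is scikit-learn; training is CPU-only and
  single-threaded, sized for cohorts of hundreds to thousands of samples.
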