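# psnet — patient classification with patient similarity networks

`psnet` classifies patients from multi-modal biomedical data (gene
expression, clinical variables, DNA methylation, rare genetic events, ...)
by turning every *feature* — a pathway's worth of measures, a single
clinical variable, or a pathway-level set of mutated genes — into a
**patient similarity network** (PSN): a weighted graph whose nodes are
patients and whose edge weights measure pairwise similarity under that
feature's data. It is aimed at computational biologists who want
interpretable, pathway-level predictors of patient class (tumour subtype,
case/control status, survival group) rather than black-box classifiers.

## Method

**Feature scoring.** For each class, a *query* (a subsample of that class's
training patients) and a *background* (the other classes' training
patients) define a pairwise regression target: +1 for query–query pairs,
−1 for query–background pairs. Candidate network edge weights are
regressed onto this target with a ridge penalty, and negative coefficients
are iteratively clipped to zero, yielding one non-negative weight per
network (the GeneMANIA-style integration recipe). Repeating over
`feat_score_max` subsamples, a feature's score is the number of queries in
which it earned a positive weight. Features that score at least
`feat_sel_cutoff` in a split are used to classify that split's held-out
patients; consensus features score high in at least `fs_pct_pass` of
splits.

**Classification.** The selected networks are rebuilt over training *and*
test patients and averaged; training membership in class *c* is propagated
by solving the regularized-Laplacian system

    (I + λL) f = y,   y_i = 1 if patient i is a training member of c

(the Gaussian-random-field formulation of semi-supervised learning). Each
test patient is assigned the class with the highest rank-normalized
propagation score.

**Sparse genetic workflow.** For rare variants, similarity is binary: two
patients are similar under a pathway iff both carry an event in its genes
(features need ≥ 6 carriers to exist). Networks are optionally filtered by
*label enrichment* — a permutation test on the member-label bias
(n₊ − n₋)/(n₊ + n₋) — and scores accumulate over folds up to
`num_splits × feat_score_max`; sweeping a cutoff over cumulative scores
yields a ROC from the rule "case ⇔ event in a selected pathway".

**Mutation smoothing.** Sparse binary mutation profiles can be
desparsified before network construction by random walk with restart over
a gene–gene interaction network, `F ← (1−r)·W·F + r·F₀`, then re-binarized
by keeping the top-scoring fraction of genes (default 3%) plus all direct
mutations.

## Worked example

```python
import psnet

ds, rules, truth = psnet.generate_synthetic_dataset(
    n_patients=60, seed=1,
    layers={"expression": {"n_features": 5, "group_size": 8,
                           "metric": "pearson"}})
clf = psnet.PSNClassifier(rules=rules, metrics=truth["metrics"],
                          num_splits=2, feat_score_max=2, feat_sel_cutoff=1,
                          random_state=1).fit(ds)
print(clf.feature_scores_["case"])
print("accuracies:", clf.result_.accuracies)
```

prints

```
                  Split1  Split2
expression_grp00       2       2
expression_grp01       0       0
expression_grp02       0       0
expression_grp03       0       0
expression_grp04       0       0
accuracies: [1.0, 1.0]
```

The cohort has one planted discriminative group (`expression_grp00`) among
four noise groups; it scores the maximum 2 out of 2 in both train/test
splits while the noise features score 0, and the held-out patients in both
splits are classified perfectly. Evaluating the two per-split prediction
tables with `psnet.evaluate_predictions(tables, "case")` gives mean AUROC
1.0 and mean AUPR 1.0 on this easy fixture.

The same loop is available from the shell:

```bash
psnet simulate --seed 1 --n-patients 60 --out cohort/
psnet build --dir cohort/ --seed 1 --out run/
```

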