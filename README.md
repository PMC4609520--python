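# acucoder

Selective deep-ensemble learning for multi-output clinical coding: annotate
ICD-10 labels and recommend acupoints from featurized clinical records.

A pool of base learners (multi-output decision trees and RBF max-margin
classifiers) is trained on bootstrap resamples of the training data. Each
learner is scored by

* **tuple accuracy** — a weighted mean of per-record indicators for the
  ICD-10 component, the diagnosis component, and the full (ICD-10,
  diagnosis) tuple; and
* **diversity** — the squared tuple Hamming distance from the full-pool
  majority vote, gated on the learner being fully correct on that record.

Learners are ranked on both metrics by a **nondominated sort** (Pareto
fronts on the rank pairs, ties broken by summed rank, then index) and
combined either by

* **top-b% majority voting** (`fit_selective_ensemble`), or
* **capacity-regularized boosting weights** (`fit_multioutput_boost`): per
  binary task, convex surrogate loss plus a per-learner complexity penalty
  minimized by cyclic coordinate descent under a nonnegativity and
  weight-sum constraint, lifted to multi-class outputs one-vs-rest.

A classical AdaBoost baseline, zero-one / Hamming loss evaluation with a
repeated ten-fold cross-validation protocol, and a seeded synthetic-data
generator (the real clinical corpus is not public) are included.

## CLI

```sh
acucoder simulate --scale small --seed 7 --out data/        # synthetic dataset + config
acucoder train --data data/dataset.csv --m-tree 10 --m-margin 10 --out pool.pkl
acucoder boost --data data/dataset.csv --pool pool.pkl --lambda 1e-3 --out boost.pkl
acucoder score-table --data data/dataset.csv --pool pool.pkl
acucoder evaluate --data data/dataset.csv --method vote --folds 10 --repeats 20 \
    --loss zero_one --report table4
```

`--scale paper` emulates the published schema: 2835 records, 21 diseases,
31 ICD-10 labels, an 11-ary basic-info vector, 4000 keyword-match bits and
53 acupoints, with the published per-disease class sizes as the prior.
A YAML file passed to `acucoder --config` supplies per-subcommand defaults;
explicit flags win.

## Layout

| module | contents |
| --- | --- |
| `acucoder.records_io` | record/dataset types, CSV I/O, keyword featurizer |
| `acucoder.synth_clinic` | seeded synthetic dataset generator |
| `acucoder.learner_pool` | bootstrap sampling, tree/margin base learners |
| `acucoder.selective_ensemble` | tuple accuracy/diversity, NDS sort, top-b% voting |
| `acucoder.deep_boost` | capacity-regularized weight solver, AdaBoost, multi-output lifting |
| `acucoder.eval_protocol` | losses, repeated k-fold protocol, report tables |
| `acucoder.benchmark` | published per-disease sizes and accuracy table (fixed inputs) |
| `acucoder.cli` | `acucoder` command-line entry point |
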