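# crpopf

Preoperative prediction of clinically relevant postoperative pancreatic
fistula (CR-POPF, ISGPS grade B/C) after pancreaticoduodenectomy.

Pancreatic fistula is the complication that drives post-Whipple morbidity,
and the strongest determinants — gland texture, duct size — are knowable
*before* the operation. `crpopf` is a small toolkit for surgical-risk
researchers that implements a fully preoperative prediction workflow:

* a **discrete Bayes classifier** over cut-off-dichotomized markers: with
  k binary markers a patient falls in one of 2^k cells, and the class with
  maximal posterior P(class)·P(cell | class) is predicted, with Laplace
  smoothing and ties resolved toward predicting a fistula;
* **leave-one-out wrapper marker selection**: every marker combination of
  size 1–3 is scored by re-substitution inside an N-fold leave-one-out
  loop (maximal sensitivity subject to specificity ≥ 50%, or maximal F1),
  and the combination selected most often across folds wins;
* the **final diagnosis-stratified model**: PDAC patients are classified by
  the MPD index alone (duct diameter / parenchymal thickness, cut-off 0.3);
  non-PDAC patients by MPD index + BMI (cut-offs 0.3 and 25 kg/m²) —
  a low MPD index flags the soft, fistula-prone gland, and in non-PDAC
  patients high BMI flags the fatty, fragile gland;
* **performance metrics** (sensitivity, specificity, PPV, NPV, F1) from
  per-stratum and pooled confusion matrices;
* a **synthetic cohort generator** that reproduces the cohort composition
  the workflow expects (marker marginals, ~47% PDAC, ~35% CR-POPF
  prevalence) with the outcome planted on configurable per-cell risks, so
  the whole pipeline is testable end-to-end without patient data.

See `docs/methods.md` for the model, its assumptions and the design
decisions.

## Worked example

Simulate a training cohort, fit the stratified model, and evaluate it on an
independent simulated validation cohort:

```sh
$ crpopf simulate --n 600 --seed 17 --out train.csv
wrote 600 records to train.csv
CR-POPF prevalence: 0.348
strata: PDAC 295, non-PDAC 305

$ crpopf fit --cohort train.csv --out model.json
model written to model.json

$ crpopf simulate --n 400 --seed 18 --out valid.csv
$ crpopf evaluate --cohort valid.csv --model model.json
PDAC: tp=28 fp=32 fn=3 tn=115
    sens 90.3% (90)  spec 78.2% (78)  ppv 46.7% (47)  npv 97.5% (97)
non-PDAC: tp=91 fp=49 fn=17 tn=65
    sens 84.3% (84)  spec 57.0% (57)  ppv 65.0% (65)  npv 79.3% (79)
pooled: tp=119 fp=81 fn=20 tn=180
    sens 85.6% (86)  spec 69.0% (69)  ppv 59.5% (60)  npv 90.0% (90)
```

Each stratum line is a confusion matrix (positive class = CR-POPF) followed
by raw metrics with half-up whole-percent renderings in parentheses. The
PDAC submodel is highly sensitive and rules the complication out well (NPV
97%); the non-PDAC submodel trades specificity for sensitivity, as a
screening rule should. The same numbers are available as JSON via `--out`,
and `crpopf select` runs the leave-one-out marker selection per stratum and
reports the per-size tallies, winners, and their held-out performance.

The same workflow is available as a library:

```python
from crpopf import (read_cohort_csv, build_final_model, evaluate_model,
                    decision_table)

training = read_cohort_csv("train.csv")
model = build_final_model(training, alpha=1.0)
print(decision_table(model))     # the model as an explicit 6-row lookup table
report = evaluate_model(model, read_cohort_csv("valid.csv"))
```

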