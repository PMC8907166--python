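# multipred

Multimodal outcome prediction with repeated nested cross-validation:
linear-SVM classifiers with greedy wrapper feature selection for tabular
modalities, a control-anchored imaging branch (proportional TIV scaling,
generalizability-theory reliability masking, empirical-Bayes site
harmonization, covariate residualization, reference-guided ICA), stacked
generalization of out-of-fold decision scores, permutation-based
significance, blocked nonparametric predictor comparisons, and
reliability-based feature importance.  A synthetic cohort generator with
known ground truth makes the entire pipeline testable end to end.

## Layout

| module | role |
| --- | --- |
| `multipred.synthcohort` | synthetic multimodal cohorts, matched reference controls, MCAR missingness injection |
| `multipred.tabprep` | fold-wise tabular preprocessing: median standardization, 7-NN imputation, pruning, min-max scaling |
| `multipred.imgprep` | TIV scaling, g-theory mask, ComBat-style harmonization, age/sex residualization, GIG-ICA |
| `multipred.cvlearn` | nested CV schemes, hinge-loss linear SVM, greedy forward wrapper over the C grid 2^-4..2^4, ensembles, stacking |
| `multipred.evalstats` | metric panel (Sens/Spec/BAC/PPV/NPV/PSI/PLR/NLR/AUC), permutation test, Quade test, rank-sum, chi-square |
| `multipred.importance` | cross-validation ratio and sign-based consistency with BH false-discovery control |
| `multipred.driver` | experiment orchestration and the `multipred` CLI |

## CLI

```bash
multipred simulate --n-subjects 109 --seed 1 --out cohort/   # write a synthetic cohort
multipred train --seed 1 --out results/ --n-perm 99 --quick  # full experiment on synthetic data
multipred apply --model ensemble.json --data clinical.csv --out scores.csv
multipred report --scores scores.csv --labels labels.csv
multipred importance --model ensemble.json --out importance.csv
```

`multipred train` trains the three unimodal predictors, the three stacked
combinations, applies everything to a validation cohort, runs permutation
tests and predictor comparisons, and writes `metrics.csv` (one row per
predictor per cohort), importance tables, and a `run_log.json` capturing
seeds and scheme parameters.

## Notes

- All randomness is funneled through explicit integer seeds; repeated runs
  are bit-identical.
- Preprocessing, harmonization, masking and residualization are fitted on
  training folds or a separate control sample only and frozen before they
  touch held-out subjects; the test suite audits this leakage contract.
- Default nested-CV geometry is 10 folds x 5 permutations at both cycles;
  tests and the quick CLI mode use reduced schemes for desk-scale runtimes.
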