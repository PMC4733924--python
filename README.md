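# metaclaims

Tools for developing and validating **administrative-claims algorithms that
detect progression to distant metastatic cancer** in patients initially
diagnosed with stage I–III breast, non-small-cell lung (NSCLC), or colorectal
cancer (CRC).

Claims databases carry no direct progression flag. The pragmatic proxy is a
*secondary-malignancy* diagnosis code (ICD-9 197–199), optionally combined
with other claims signals — a second primary tumor at a different site,
treatment changes, palliative-care markers — under a temporal template: a
radiology or pathology *anchor* claim at least 60 days after the initial
diagnosis (the *index date*), followed by the qualifying element within 30
days. This package implements the full development-and-validation loop for
such algorithms, exercised on synthetic cohorts that emulate the statistical
structure of a published single-system validation study, with chart-review
progression status as the reference standard.

Intended users: pharmacoepidemiologists and health-services researchers who
build or audit claims-based phenotypes for oncology outcomes.

## What is inside

| module | role |
| --- | --- |
| `metaclaims.synthetic_claims` | synthetic cohorts (patients, claim streams, reference outcomes) with configurable conditional indicator prevalences; deterministic fixtures that realise an exact 2×2 table end to end |
| `metaclaims.cohort_builder` | eligibility screening (age ≥ 18, stage I–III, ≥ 90 days post-index enrollment, 60-day metastatic washout) with an exclusion audit log |
| `metaclaims.feature_engine` | anchor–lag construction of the ~27 binary progression indicators, including treatment-initiation and chemotherapy-regimen-change logic |
| `metaclaims.rf_pipeline` | pre-balanced repeated random-forest permutation importance; synthetic-forest ranking of individual trees as candidate algorithms |
| `metaclaims.algorithm_eval` | the candidate models as boolean rule trees, timing-matched classification (±90 days around the progression date), sensitivity/specificity/PPV/NPV |

The statistical core, in the field's usual notation: each forest is grown on
a *pre-balanced* sample (all `n₁` progressed patients plus an equal-size
draw of the non-progressed), permutation importance for variable `j` is the
mean over trees of the decrease in out-of-bag accuracy after permuting
`x_j`, averaged over 100 balanced forests of 1000 trees; a *synthetic
forest* then treats each saved tree's per-patient prediction as a predictor
variable in a second forest, so that tree-level importances rank the 1000
branching algorithms, and trees ranking consistently highly across repeated
balanced runs are short-listed. Performance of a final rule `R` is read off
the 2×2 table where a progressed patient counts as a true positive only if
`R`'s detection date `t_R` satisfies `|t_R − t_prog| ≤ 90` days.

## Worked example

Reconstruct the breast-cancer secondary-malignancy model's published 2×2
table from its cohort margins (17 progressed / 485 not) and printed rates,
realise it as a claims cohort, and push it back through the whole pipeline:

```python
import metaclaims as mc
from metaclaims.algorithm_eval import evaluation_report

cm = mc.reconstruct_confusion(17, 485, 64.7, 86.0)     # -> (tp=11, fp=68, fn=6, tn=417)
model1 = mc.builtin_algorithms(mc.TumorType.BREAST)[0]  # secondary_malignancy
patients, outcomes = mc.generate_fixture_confusion(
    mc.TumorType.BREAST, model1, cm.tp, cm.fp, cm.fn, cm.tn, seed=7)
eligible, _ = mc.apply_eligibility(patients, outcomes)
features = [mc.extract_features(p) for p in eligible]
print(evaluation_report(features, outcomes, [model1]).to_string())
```

```
                                      rule  tp  fp  fn   tn  sensitivity  specificity   ppv   npv
tumor_type algorithm
BREAST     model_1    secondary_malignancy  11  68   6  417         64.7         86.0  13.9  98.6
```

Reading: of 17 patients who truly progressed, the claims rule detects 11
within ±90 days of the chart-review progression date (sensitivity 64.7%);
because progression is rare (3.4%), only 13.9% of rule-positive patients
truly progressed (PPV), while a negative call is almost always right
(NPV 98.6%).

A CLI mirrors the library:

```bash
metaclaims generate --tumor-type breast --profile published --seed 1 --out cohort/
metaclaims cohort   --in cohort/ --out eligible/
metaclaims features --in eligible/ --window 60 --out features.csv
metaclaims importance --in eligible/ --n-forests 100 --n-trees 1000 --out importance.csv
metaclaims evaluate --in eligible/ --match-window 90 --out report.csv
```

## Limitations

Events are semantic categories, not real ICD-9/CPT/NDC codes (a
code-to-category mapping layer is intentionally out of scope), and the
synthetic cohorts reproduce marginal prevalences conditional on progression
but not the correlation structure of real claims. See `docs/methods.md` for
the full modelling assumptions and design decisions.
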