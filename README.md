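# geritox

Chemotherapy-toxicity risk scoring and diagnostic-accuracy evaluation for
older cancer patients.

Oncologists treating patients over 70 need to anticipate who will tolerate
chemotherapy and who will end up with severe toxicity, an emergency-department
visit, a hospital admission, or early treatment discontinuation. `geritox`
implements two bedside risk scores and the complete statistical apparatus for
evaluating and comparing them on a cohort, plus a calibrated simulator for
generating realistic patient-level data when only aggregate tables are
available.

## The scores

**Index4** is a four-item count, 1 point each:

| item | criterion |
|---|---|
| performance status | ECOG PS > 1 |
| renal function | creatinine clearance < 40 mL/min |
| nutrition | albumin < 35 g/L |
| extent of disease | stage 4 |

`Index4 = 0` versus `>= 1` is the working dichotomy.

**CARG** (Cancer and Aging Research Group) is an 11-item weighted sum:
3 points each for hemoglobin < 11 g/dL (men) / < 10 g/dL (women), creatinine
clearance < 34 mL/min, and >= 1 fall in 6 months; 2 points each for age > 72,
GI/GU cancer, standard (non-reduced) dose, polychemotherapy, hearing fair or
worse, and limited one-block walking; 1 point each for needing help with
medications and decreased social activity. Categories: low 0–5,
intermediate 6–9, high >= 10. All cut-offs are strict inequalities; boundary
values score nothing.

## The statistics

For a dichotomised score against a binary outcome the package computes the
2×2 table and sensitivity / specificity / PPV / NPV / accuracy; empirical ROC
curves with the trapezoidal AUC (= Mann–Whitney concordance with ties counted
½) and a DeLong or bootstrap 95% CI; and the paired comparison of the two
tools on the same patients via the exact McNemar test: with *b* patients
classified correctly by Index4 only and *c* by CARG only,

```
p = 2 · P( X <= min(b, c) ),  X ~ Binomial(b + c, ½)        (capped at 1)
OR = b / c      (> 1 favours Index4)
```

with an exact conditional 95% CI (Clopper–Pearson on the discordant split,
mapped to odds). Group contrasts use Fisher's exact test (2×2), Pearson χ²
(larger tables), the t-test (2 groups) or one-way ANOVA (3+).

## Worked example

```bash
geritox simulate --n 117 --seed 42 --out cohort.csv
geritox score --in cohort.csv --out scores.csv
geritox evaluate --in cohort.csv --outcome grade34 --report report.txt
cat report.txt
```

```
outcome: grade34_ae (n=117)
       carg_high  sens 52.2  spec 79.2  ppv 78.3  npv 53.5  acc 63.2
   carg_int_high  sens 85.5  spec 29.2  ppv 63.4  npv 58.3  acc 62.4
      index4_ge1  sens 50.7  spec 60.4  ppv 64.8  npv 46.0  acc 54.7
  AUC index4: 0.543 (95% CI 0.445-0.642)
  AUC carg: 0.677 (95% CI 0.579-0.774)
  McNemar carg_high vs index4_ge1 [outcome_present_only]: b=15 c=16 p=1 OR=0.9375
  McNemar carg_int_high vs index4_ge1 [outcome_present_only]: b=4 c=28 p=1.93e-05 OR=0.14285714285714285
  McNemar carg_low vs index4_eq0 [outcome_absent_only]: b=20 c=5 p=0.004077 OR=4.0
  McNemar carg_low_int vs index4_eq0 [outcome_absent_only]: b=5 c=14 p=0.06357 OR=0.35714285714285715
```

Reading this: on this simulated 117-patient cohort a high CARG score predicts
grade 3–4 toxicity with 52.2% sensitivity and 79.2% specificity, while
Index4 ≥ 1 trades specificity for simplicity. The last McNemar line but one
says that among patients *without* toxicity, 20 were flagged correctly
(score 0) by Index4 only versus 5 by CARG only — Index4 is significantly
better at ruling out toxicity here (OR 4.0, p ≈ 0.004).

The same cohort can be scored in Python:

```python
from geritox import PatientRecord, index4_score, carg_score

p = PatientRecord(age=75, sex="male", cancer_type="GI", stage="4", ecog_ps=1,
                  hemoglobin=10.0, creatinine_clearance=55.0, albumin=33.0,
                  falls_past_6mo=False, hearing_fair_or_worse=False,
                  walking_one_block_limited=True, needs_help_medications=False,
                  decreased_social_activity=True, polychemotherapy=True,
                  standard_dose=True)
index4_score(p).total   # 2   (albumin < 35, stage 4)
carg_score(p).total     # 14  -> "high"
```

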