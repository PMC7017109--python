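# oncomatch

Decision-support computations for precision oncology: a biomarker–drug
**matching score** that rates how completely a drug regimen covers the
pathogenic molecular alterations of a tumor, an exhaustive
**combination-ranking engine** with clinical eligibility constraints, and the
**retrospective validation statistics** (RECIST-based outcome classification,
confusion matrices, Clopper–Pearson intervals, ROC/AUC, Youden thresholding,
Mann–Whitney tests) used to evaluate such scores against treatment-history
cohorts. A seeded synthetic-cohort simulator makes every analysis runnable
without access to patient data.

It is written for bioinformaticians and methods researchers who want an open,
testable implementation of this family of rule-based therapy-matching scores —
production knowledge bases behind commercial platforms are proprietary, but
the arithmetic is not.

## The matching score

A patient profile contributes a set of *scoreable biomarkers*: pathogenic,
gene-level alterations (negative/normal findings such as Her2-negativity are
reported but never scored). For a regimen R and profile with biomarkers
b₁…b_n the score is

```
score(R) = round( 100 × Σᵢ min(c, Σ_{d∈R} h(d, bᵢ)) / (w_direct × n) )
```

where the per-drug hit h(d, b) is `w_direct` (default 1.0) when d targets the
altered gene product directly (low-nanomolar IC50 target, antibody epitope,
or validated sensitivity biomarker), `w_indirect` (default 0.5) when d
targets a co-member of the altered gene's signaling pathway, and 0 otherwise;
a resistance rule nullifies every contribution of the drug. The per-biomarker
cap `c` (default 1.0) prevents double counting, so a regimen matching every
alteration scores exactly 100%. Named multiplicative modifiers (age-class /
allergy / route eligibility, optional drug-count penalty) can scale the
pre-rounding ratio. Treatment lines are classified *successful* when they end
in complete or partial response or in stable disease lasting ≥ 12 months, and
the score is then evaluated as a diagnostic test for that label.

## Worked example

The package ships a 10-drug calibration knowledge base and the profile of a
hormone-receptor-positive metastatic breast-cancer case (`P51`): ER+ and PR+
expression, *PTEN* copy loss, and *CCND1*/*FGFR1*/*PRKDC* amplifications —
six scoreable biomarkers.

```
$ oncomatch score --kb kb.json --profile profiles.tsv --patient P51 \
      --regimen "anastrozole+everolimus"
{
 "regimen": "anastrozole+everolimus",
 "score_percent": 42,
 "numerator": 2.5,
 "denominator": 6.0,
 "matched_biomarkers": ["ER", "PR", "PTEN"],
 ...
}
```

Anastrozole hits ER directly (1.0) and PR indirectly (0.5), everolimus hits
the PTEN loss directly (1.0): 2.5 of a maximum 6 gives 42%. Single-agent
tamoxifen covers only ER, 1/6 → 17%; the cytotoxic regimens (FAC,
capecitabine, cisplatin) match nothing and score 0%. Ranking all one- and
two-drug combinations recovers the combination as the top candidate:

```
$ oncomatch rank --kb kb.json --profile profiles.tsv --patient P51 --max-drugs 2 --top 3
rank  regimen                 score_percent  matched_biomarkers
1     anastrozole+everolimus  42             ER,PR,PTEN
2     everolimus+tamoxifen    33             ER,PTEN
3     anastrozole             25             ER,PR
```

`oncomatch simulate` writes a seeded synthetic cohort (70 patients, ~3
treatment lines each, ~4 pathogenic alterations per tumor, logistic
score–outcome model calibrated to an AUC of about 0.85) and
`oncomatch evaluate` produces the full validation report for any scored
cohort TSV.

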