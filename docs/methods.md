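# Methods

## Scoring model

The matching score treats a regimen as a set of drugs and a tumor profile as
a set of pathogenic, gene-level biomarker calls. Per biomarker and drug the
model assigns a *hit*: the direct weight when a curated rule says the drug
acts on the altered product itself (low-nanomolar IC50 target, antibody
epitope, or a clinically validated sensitivity biomarker), the indirect
weight when the drug targets a co-member of the altered gene's signaling
pathway, zero otherwise. Hits are summed over the drugs of a combination and
capped per biomarker; the capped sum over biomarkers is normalized by the
maximum attainable hit score, `direct_weight × n_biomarkers`, and reported
as an integer percentage (half-up rounding, since published scores are
integer percentages).

Assumptions worth making explicit:

- **Additivity with a cap.** Drug effects on distinct biomarkers add;
  redundant coverage of the same biomarker does not. This makes "covers the
  whole profile" identical to 100% and bounds every score in [0, 100].
- **Weight conventions.** Published case series print scores but never the
  weight constants. `direct = 1.0`, `indirect = 0.5`, `cap = 1.0` is the
  minimal scheme under which all four printed scores of the packaged
  worked-example case reproduce (17% single-agent hormone therapy, 42% for
  the two-drug combination, 0% for unmatched cytotoxics, 100% for full
  coverage). They are package conventions, exposed in `ScoringConfig`.
- **Denominator.** Only pathogenic, non-negative findings count. The
  worked-example case only reproduces its printed scores with a six-element
  denominator, which requires counting hormone-receptor positivity (ER and
  PR) as scoreable biomarkers and excluding the Her2-negative finding; the
  packaged fixture documents this inference.
- **Resistance.** A resistance rule matching anywhere in the profile
  nullifies the whole drug, not just one biomarker — a deliberately
  conservative convention.
- **Empty profiles are an error.** A score of 0 means "nothing matched";
  an undefined denominator must not silently collapse onto it.

Clinical fine-tuning beyond the ratio is modelled as an ordered registry of
named multiplicative modifiers on the pre-rounding ratio, each returning a
factor in [0, 1]. Shipped: `eligibility_zero` (adult-only drug for a
pediatric patient, allergy, or no acceptable administration route → factor
0) and `drug_count_penalty` (geometric penalty per drug beyond the first,
default 1.0 = off). Both default off, which preserves the monotonicity
property that adding a drug never lowers a score. The proprietary
"multi-parametric" tuning used by commercial platforms is not reconstructible
from public sources; the registry is the pluggable stand-in surface for it.

## Knowledge base

Drugs, pathways (gene sets), and match rules
`(drug, gene, alteration_class) → direct/indirect/resistance` with optional
per-rule weight overrides. Canonical serialization is one JSON document; a
flat TSV export (`drugs.tsv`, `pathways.tsv`, `rules.tsv`) exists for
spreadsheet curation. Pathway-derived indirect rules can be expanded
explicitly (`derive_indirect_rules`): for each direct rule and pathway
co-member, indirect rules are generated for *activating* alteration classes
only (activating mutation, amplification, fusion, over-expression).
Loss-of-function classes are never auto-derived — whether losing a
co-pathway gene sensitizes or de-sensitizes to a drug is not decidable from
membership alone and must be curated (the packaged everolimus–PTEN rule is
such an explicit curation). Derivation is idempotent and never overrides an
explicitly curated (drug, gene) pair.

The packaged calibration knowledge base contains 10 drugs (two hormone
agents, an mTOR inhibitor, an anti-HER2 antibody, six rule-less cytotoxics),
four toy pathways and five rules — the minimal set that reproduces the
worked example. It is a fixture, not a clinical resource.

## Combination ranking

Candidates are all subsets of the eligible drugs up to `max_drugs`
(default 3), with at most one hormone-class agent per regimen by default.
Eligibility filtering (allergies, adult-only drugs for pediatric patients,
administration routes) happens before enumeration; enumeration order is
deterministic (size, then lexicographic). Scoring of the space is vectorised
(per-drug contribution vectors, capped sums via numpy); the scalar and
vectorised paths are property-tested for equality, and a 230-drug space
(Σ₁³ C(230,k) = 2,028,025 candidates) scores in a few seconds on one core,
so enumeration is exhaustive with no pruning heuristics. Ranking sorts by
score, then fewer drugs, then label — the tie-break is a convention chosen
for determinism and the preference for minimal regimens.

## Validation statistics

Outcome labels: CR/PR, or SD lasting ≥ 12 months, are successes; everything
else (including SD of 6–12 months) is a failure. The score is then treated
as a diagnostic test. Conventions and numerical choices:

- Prediction at a threshold is **strict** (`score > t`): with integer scores
  and a 25% operating point, exactly-25 is predicted unfavorable.
  Configurable.
- Confidence intervals for sensitivity/specificity/PPV/NPV are exact
  binomial (Clopper–Pearson, `statsmodels` beta method). Undefined metrics
  (zero denominator) are returned as `None`, never NaN.
- The ROC curve comes from all distinct score thresholds
  (`sklearn.metrics.roc_curve`); the AUC is computed through the
  Mann–Whitney identity `AUC = U / (n₁·n₂)` with tied pairs counted ½, and
  tests assert its exact agreement with trapezoidal integration of the
  curve.
- Youden threshold selection scans the distinct observed scores (plus one
  value below the minimum) and maximizes sensitivity + specificity − 1,
  breaking ties toward the lowest threshold.
- Mann–Whitney U is reported in both orientations plus the conventional
  smaller value; p-values use the tie-corrected normal approximation, or
  exact enumeration of all group assignments (valid under ties) when
  n₁·n₂ ≤ 100. No multiplicity correction is applied: the design has a
  single pre-specified comparison.

## Synthetic cohorts

The generator emulates the statistical skeleton of a curated
exceptional-responder cohort: 70 patients; treatment-line counts
zero-truncated geometric with mean 3, right-censored at 14; alteration
counts 1 + Poisson(3) (mean 4, support ≥ 1); biomarkers drawn without
replacement from a gene × class frequency table of actionable markers and
non-actionable passengers; every profile carries at least one actionable
marker, as a curated molecularly-informed cohort presupposes. Regimens mix
*targeted* selection (drug choice weighted by actual profile hits,
probability 0.6) with *empiric* uniform selection — the mix is what spreads
scores over their full range, as physician-selected matched therapies do in
real cohorts. Scores are always computed through the scoring pipeline, never
assigned. Outcomes follow a logistic model
`P(success) = expit(a + b·score/100)` — the simplest monotone link for
"higher score, better response" — with response class and duration sampled
consistently with the drawn label. All randomness flows from one seed
through a single `numpy.random.Generator`.

Defaults `a = −2.6`, `b = 9.0`: the slope comes from
`calibrate_outcome_model` (monotone bisection against a mean-AUC target of
0.85); the intercept puts the success-probability crossing of the cohort
base rate near a score of 25, where Youden selection then lands, and gives
zero-score lines a ~7% success probability (unmatched regimens occasionally
succeed). With these defaults a simulated cohort recovers AUC 0.85 ± 0.05
and a Youden threshold in [15, 35] in about 90% of seeds — the residual
misses are irreducible at this cohort size, since the sampling standard
deviation of an AUC-0.85 estimate at ~210 records is ≈ 0.03.

What passing on synthetic cohorts does **not** show: the generator plants a
clean monotone score–outcome link, has no per-histology drug effects, no
confounding between line number and outcome, and no correlation structure
beyond profile sharing within a patient. Recovery of the planted signal
validates the statistical machinery, not the clinical validity of any
score on real patients.

## Problem sizes

Default test and acceptance runs use the packaged 10-drug knowledge base,
synthetic cohorts of 70 patients (~210 treatment lines), 50-seed recovery
sweeps, and one full 230-drug (2,028,025-regimen) exhaustive scoring pass —
sizes chosen so the whole suite completes in well under a minute of compute
while still exercising the realistic combination-space scale.

## Known limitations

- The packaged knowledge base is a calibration fixture; clinical use would
  require a curated drug–biomarker database orders of magnitude larger.
- Weight constants and several conventions (strict thresholding, resistance
  nullification, tie-breaks) are documented package choices, not published
  values; alternatives are configurable but untested against external data.
- Published cohort-level statistics that depend on per-regimen appendix data
  (overall U statistics, group medians/means) have no machine-readable
  source and are not reproduced, only emulated in distribution.
- No dosing, scheduling, pharmacokinetics, drug–drug interactions, or
  survival modelling.
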