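# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic cohorts do and do not emulate.

## Problem setting

Patients enter at an *index date* — the initial diagnosis of stage I–III
breast, non-small-cell lung, or colorectal cancer — and are followed through
enrollment in a claims-paying health plan. The outcome is progression to
distant metastasis, determined by chart review (the reference standard),
with a progression date. The task is to detect that outcome, and roughly
its date, from claims alone.

## Temporal indicator model

All claims are abstracted to semantic categories (diagnosis / procedure /
pharmacy, e.g. `SECONDARY_MALIGNANCY_DX`, `RADIOLOGY`, `OPIOID`,
`CHEMO_AGENT`). Dates are integer days since an arbitrary epoch; only
differences matter, and every window below is closed (both endpoints
included).

* **Anchor**: any radiology or pathology claim at day
  `t ≥ index + anchor_min_days_after_index`. Default 60 days; the
  sensitivity-analysis grid is {60, 90, 120, 180, 365}. Day `index+60`
  itself qualifies.
* **Element lag**: an indicator fires when a qualifying event falls in
  `[a, a + 30]` for *some* anchor `a` (an element may pair with any anchor,
  not only the first; day `a+30` qualifies).
* **Initiation** variants additionally require no same-category event at
  any strictly earlier date.
* **Chemotherapy regimens**: consecutive `CHEMO_AGENT` dispensings ≤ 60
  days apart form one regimen; a regimen's agent set is the distinct agents
  within its first 90 days. *Change in chemotherapy* fires when a regimen
  whose start lies in an anchor window has a different agent set from the
  immediately preceding regimen; *multidrug→single* additionally requires
  the prior set to hold ≥ 2 agents and the new set exactly one. The gap
  (60 d) and agent-set window (90 d) are modelling choices of this package
  — "regimen" has no canonical claims definition — and are configurable.
* The *first-trigger date* of an indicator is the earliest qualifying
  element date; a compound rule's detection date combines triggers with max
  over AND children and min over satisfied OR children (an AND is satisfied
  once its last conjunct is).

The catalogue holds 27 indicators plus the anchor-presence
pseudo-indicator; tumor-type restrictions follow clinical applicability
(airway management and parenteral feeding: lung only; hormonal/immuno
initiation, site-specific pain, lump, dyspnea: breast only;
multidrug→single: breast and lung). "More invasive surgery" and "surgery at
a non-primary site" are modelled as one `SURGERY`-based pair distinguished
by the site attribute; laterality is collapsed so that a contralateral
breast/lung malignancy is `PRIMARY_SITE` and never counts as a different
site.

For delayed anchor windows (> 60 days) the evaluation cohort additionally
drops patients who progressed or were lost to follow-up within 365 days of
index, applied uniformly across all delayed windows: a delayed anchor
cannot observe such patients at all.

## Eligibility

Eligible patients are adults (≥ 18 y) with stage I–III disease, enrollment
covering the index date and extending ≥ 90 days past it ("fewer than 90
days" excludes a gap of ≤ 89; day 90 survives), no second-primary claim on
or before index, and no metastatic evidence — a secondary-malignancy claim
*or* reference-standard progression, applied conservatively as both — on or
before `index + 60` (day 60 inclusive). When a patient fails several
criteria the recorded reason is the first in the listed order, with all
failed criteria kept in a secondary field.

## Synthetic cohorts

The real study population is not deposited anywhere, so the generator
emulates its statistical skeleton:

* Cohort sizes and progression prevalences: 502 (17 progressed), 236 (61),
  279 (33) for breast / NSCLC / CRC. The source reports CRC progression
  both as 12.0% (33/276) and 11.8% (33/279); the generator uses 279
  eligible with 33 progressed and leaves the discrepancy unresolved.
* Per-indicator prevalences conditional on progression status are the
  published conditional frequencies; indicators are drawn independently
  given status (only marginals are published), except that initiation of
  radiation is drawn inside radiation-any and multidrug→single inside
  chemotherapy-change, preserving marginals while keeping the logical
  implications consistent.
* Post-index enrollment is log-normal calibrated to the published
  median/IQR (35.7 (20.0–59.9), 17.6 (8.6–33.1), 30.7 (16.5–53.4) months),
  `μ = ln(median)`, `σ = ln(q₃/q₁)/(2 z₀.₇₅)`, truncated at ≥ 120 days —
  eligibility alone needs 90, and the headroom guarantees room for an
  anchor-plus-lag pattern. Index dates are staggered uniformly over an
  eight-year accrual window; enrollment starts 180–365 days before index.
* Each positive indicator draw is realised as a concrete pattern (anchor
  claim, then the qualifying element inside the 30-day lag) so that the
  feature engine recovers exactly the drawn set; negative draws leave no
  qualifying pattern. Patients drawing "radiation any" without "initiation"
  get a pre-index radiation course as the blocker. A patient who draws any
  positive indicator necessarily carries an anchor claim even if the anchor
  coin said no; anchor prevalence is 96–100% in every published stratum,
  so the distortion is negligible.
* Progression dates are uniform over `(index + 60, enrollment_end]` (the
  source does not characterise progression timing). A progressed patient's
  secondary-malignancy claim, when drawn positive, is placed within ±20
  days of the progression date so that timing-matched evaluation can
  succeed; all other indicators are placed uniformly over follow-up.
* Infeasible timeline draws are resampled up to 100 times per patient,
  then rejected with a diagnostic.

What the generator does **not** emulate: correlation between indicators
beyond the two logical couplings, real billing-code noise (miscoding,
rule-out codes), care fragmentation, seasonal claim density, death or
disenrollment dynamics, or site-specific coding practice. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under the published marginal structure — not the field accuracy of
any algorithm on real claims.

A second generator builds exact fixtures: given a rule and requested
(TP, FP, FN, TN) cells it constructs progressed patients with all of the
rule's leaf patterns triggering 10 days after the progression date (TP),
progressed patients with no pattern (FN), non-progressed with (FP) and
without (TN) the pattern, so the full pipeline reproduces the requested
table exactly. This is how the published worked examples are exercised end
to end.

## Random-forest procedure

* **Pre-balancing**: every forest trains on all minority-class patients
  plus an equal-size without-replacement draw of the majority class; a
  fresh draw per forest.
* **Importance**: classical permutation importance — per tree, the decrease
  in out-of-bag accuracy when one variable's values are permuted within the
  tree's OOB rows, averaged over trees, then averaged over forests. Raw
  (unscaled) importances are used; the alternative z-scored variant is not.
  The replication-scale configuration is 100 forests × 1000 trees; the test
  suite runs a scaled-down 10 × 100 configuration, which is ample for the
  planted-signal properties it checks.
* Forests are assembled from individual CART trees (`max_features = √p`)
  with explicit bootstrap bookkeeping, so OOB membership and per-tree
  predictions are directly available. OOB vote ties break to the positive
  class; constant variables are retained with ≈ 0 importance, never
  silently dropped.
* **Synthetic forest**: on a 2–3 variable subset, a preliminary balanced
  forest is fitted and saved; the patients × trees matrix of per-tree
  predicted classes becomes the design matrix of a second forest, whose
  permutation importances score the saved trees. The procedure repeats over
  5 balanced samples by default (the repetition count is not specified in
  the source; 5 is this package's default, configurable). Runs whose
  synthetic-forest OOB error differs from the preliminary forest's by more
  than 0.05 absolute ("widely different", quantified here) are discarded.
* Saved trees are deduplicated by truth-table equivalence over the subset
  variables; a rule's per-run score is the best among its copies, and its
  rank history across retained runs feeds selection: short-listed rules
  rank within the top 10% of distinct rules (at least the single top rule)
  in ≥ 80% of retained runs.
* Extracted rules are exact truth-table equivalents of their source trees.
  Monotone tables are rendered as positive DNF over the minimal true
  points; non-monotone tables fall back to a minterm DNF with NOT literals,
  and constant trees become TRUE/FALSE nodes. Detection-date semantics are
  defined only for monotone (AND/OR/LEAF) rules — the absence of a claim
  has no date.
* Seeds propagate hierarchically (master seed → per-forest/per-run
  substreams); identical inputs and seed give identical results.

## Evaluation conventions

* Timing match: TP requires `|detection − progression| ≤ 90` days (both
  boundaries inclusive). A mistimed positive in a progressed patient is
  counted FN by default — the detection failed at the required time — with
  an FP-style accounting available as a sensitivity analysis; the source
  does not state which it used. The match is applied uniformly to all
  models.
* Sens/spec/PPV/NPV are percentages rounded half away from zero to one
  decimal; a measure with denominator zero is undefined and reported as
  missing, never 0.
* `reconstruct_confusion` inverts printed rates: `TP = round(sens·n₊/100)`,
  `TN = round(spec·n₋/100)` (round half away from zero), complements for
  FN/FP. For the published cohort sizes this is verified to be the unique
  integer table whose rates round back to the printed one-decimal values.

## Known limitations

* Semantic event categories stand in for code lists; a code→category
  mapping config is a stub by design.
* Only age/sex/tumor-type demographics are modelled; no race, smoking,
  comorbidity or cost fields, no death modelling.
* The delayed-window (≥ 120 day) sensitivity results depend on an exclusion
  rule whose exact published window is ambiguous; the package reproduces
  the mechanism but makes no quantitative claim there.
* Prior-literature comparison algorithms are out of scope.
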