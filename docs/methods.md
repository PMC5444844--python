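# Methods

## Data model

A registry is one row per pregnancy record: opaque `pregnancy_id` and
`mother_id`, a parity stratum (primiparous / multiparous), a binary
preeclampsia (PE) outcome, and thirteen binary exposure flags — age ≥ 40,
low education (≤ 11 years), non-cohabiting, diabetes mellitus, chronic
hypertension, autoimmune disease, chronic kidney disease, obesity
(BMI ≥ 30), previous PE, smoking, multiple pregnancy, ART conception and
gestational diabetes.  Raw fields (maternal age, BMI, education years,
ICD-10 code lists) may be supplied instead and are resolved by
`registry.dichotomize` / `registry.apply_icd_codes`.

ICD-10 handling: PE/eclampsia is O14/O15 and takes precedence over a
concurrent O13 (gestational hypertension) code; O11/O12/O13 are non-PE
hypertensive disorders; O16 (unspecified maternal hypertension) counts as
chronic hypertension.  Disease exposures map category-wise — I10–I15
chronic hypertension, E10–E14 diabetes, N18/N19 CKD, M32/M05/M06 plus
D68.6 autoimmune, O24 gestational diabetes.  Matching is by 3-character
category prefix because registers store 4–5 character codes; D68.6 is
matched at 4 characters since the D68 category is broader than
antiphospholipid syndrome.  The same PE-wins precedence is applied to O11
as to O13; the source data conventions do not pin this case down, so it is
an explicit assumption of the implementation.

Validation rejects (never imputes) missing flags, previous PE in a
primiparous record, and — unless multiple-birth rows are expected —
duplicate pregnancy ids.  Multiple births are reduced to one record per
pregnancy by seeded random selection (`select_one_per_pregnancy`);
`select_one_per_mother` analogously yields a cluster-independent subset.

## Synthetic generator

The generator's defaults *are* the study conditions of the published
Swedish cohort summary shipped in `mbr_summary`:

* exposures: independent Bernoulli at the published per-stratum margins
  (only margins are published, so independence is the default; an
  exchangeable Gaussian-copula `exposure_corr` hook exists, off by
  default);
* outcome: Bernoulli(expit(β₀ + Xβ)) with β = ln(published mutually
  adjusted ORs) — adjusted rather than crude, because those are the
  coefficients of the published multiple model;
* intercept β₀: calibrated per stratum by exact enumeration of the 2^k
  exposure cells and monotone root-finding (Brent), so the expected
  incidence equals 2.41 % (multiparous) / 5.57 % (primiparous) to ~1e-12;
* clustering: multiparous mothers contribute 1–4 pregnancies with
  truncated-geometric sizes (decay 0.5 by default; the real distribution is
  unpublished, so this is a documented knob); primiparous mothers
  contribute one.  Exposures are drawn independently across a mother's
  pregnancies — real sisters-births correlate, so the synthetic design
  *understates* intra-mother correlation and cluster-robust SEs exceed
  model SEs only mildly;
* multiple-birth duplicate rows (twins sharing a `pregnancy_id`) are
  emitted only when `emit_multiple_birth_duplicates=True`, so default
  stratum sizes are exact pregnancy counts.

One `numpy` generator per run with a fixed stream order (exposures,
outcomes, cluster sizes; strata in listed order) makes the output CSV
byte-reproducible under a seed.  `expected_da` gives closed-form population
accuracy of any marker under this model by the same cell enumeration, and
is the oracle the simulation is tested against.

What passing tests on these data do **not** show: real exposures are
correlated (obesity–diabetes, age–parity), effects may not be exactly
logistic-additive, and registry coding error is absent here.  Parameter
recovery and rank-recovery results therefore validate the *estimators
under the stated model*, not the published point estimates; the published
registry AUCs (75.35 / 61.48) and figure-level forest orderings are not
reproducible without the records and are deliberately out of scope.

## Accuracy statistics

Point estimates as in the README table; percentages are carried in
percent.  Confidence intervals: Wilson score for TPF/FPF/AR, a normal
interval on the difference of independent proportions for AF, Simel-type
log intervals for both likelihood ratios
(var(ln LR+) = (1−TPF)/tp·... cellwise as fn/(n₁·tp) + tn/(n₀·fp)),
and a Woolf log interval for the OR.  Empty cells: the point estimate is
reported as-is (`inf`/`nan` sentinels where undefined); only the interval
uses a 0.5 continuity correction.  A display helper prints percentages
below 0.05 as "~0", matching screening-table convention.  The published
tables' 2×2s are rebuilt as tp = round(AR% × n_group), fp = n_group − tp,
fn = cases − tp, tn = rest; with AR printed to 3 significant digits the
induced error on LR± is well under 2 % for every targeted row.  (One
published TPF cell, previous PE 19.7 (28.7–30.7), is inconsistent with its
own CI and with reconstruction (≈ 29.7); it is treated as a typo and not
targeted.)

## Logistic modelling

Fits are maximum likelihood via IRLS (statsmodels GLM/Binomial, tol 1e-10,
max 100 iterations); non-convergence or |β̂| > 30 raises a separation
error rather than returning garbage.  The cluster-robust covariance is the
CR0 sandwich — bread = inverse information, meat = outer products of
mother-cluster-summed scores — with no small-sample correction, since
cluster counts are in the tens of thousands in the intended regime.  With
singleton clusters CR0 reduces algebraically to the HC0 heteroskedasticity
sandwich (not to the model covariance; the two agree only asymptotically
under correct specification, and the tests check both facts separately).

Backward elimination starts from the saturated model, repeatedly drops the
single candidate with the largest robust Wald p ≥ 0.1 and refits; forced
covariates (smoking, education, cohabitation) are never dropped; p-ties
break toward the smaller |β̂|.  Wald-on-robust was chosen over LRT because
robust SEs are the stated inferential basis, and an LRT is not valid under
a working-independence likelihood.

AUC is the tie-corrected Mann–Whitney statistic computed from midranks —
identical to all-pairs concordance, which the tests verify by brute force —
and sensitivity at FPF = 10 % reads the empirical ROC step function
(largest FPF ≤ 0.10).  Centile rules use the nearest-rank percentile
within the parity stratum and flag strictly above the cutoff, so an
all-ties vector flags nobody; cutoffs are computed per stratum because the
predicted-probability scales of the two strata differ.

## Interaction

For stratifier i (primiparity) and factor j, one logistic model with both
main effects and the product term gives OR10, OR01, OR11 against the
doubly-unexposed cell.  Ratio of ORs = exp(product coefficient) with its
Wald CI; ICR = OR11−OR10−OR01+1 with a delta-method CI on the OR scale,
gradient (OR11−OR10, OR11−OR01, OR11) against the (robust, when clusters
are supplied) coefficient covariance.  The delta method was applied on the
OR scale because the ICR is defined there; the cluster bootstrap agrees
with it within 15 % of the half-width on synthetic data at n = 10⁵.  A
scale is called positive/negative when its CI excludes the null (1 or 0)
and "absent" only at exact equality; the two scales may disagree in sign,
which is reported, not reconciled.  Previous PE is excluded from the
parity-interaction loop since it is undefined in primiparous pregnancies.
Empty cells make the model inestimable and raise an error naming the cell.

## Rules and subgroups

Major factors: previous PE, CKD, autoimmune disease, diabetes, chronic
hypertension.  Moderate: age ≥ 40, obesity, multiple pregnancy, ART,
gestational diabetes (family history and inter-pregnancy interval are not
in the data model; ART and gestational diabetes stand in, as in the
recreated guidelines).  Parity itself is never counted inside a stratified
analysis.  Combination subgroups use exact-match semantics — a record
belongs to mask (1,0,1,1) only if its four flags equal the mask — with the
all-false mask as reference and accuracy computed against the whole
stratum, so row counts plus the reference reconcile to the stratum N.
Adjusted ORs come from a single per-stratum fit with one indicator per
estimable combination plus the three social covariates only (adjusting for
the remaining clinical factors would condition on components of the
combinations themselves); all-case or all-control cells would separate the
likelihood and are reported with accuracy statistics but no adjusted OR.

## Random forest

Implemented from first principles because every feature is binary: Gini
CART (G = 2p(1−p)) on bootstrap resamples, `mtry` = ⌈√p⌉ features per
node, `min_leaf` = 50, 500 trees by default (200 in the pipeline driver).
Importance is mean decrease in Gini — impurity decrease weighted by the
fraction of the tree's samples at the node, summed over splits, averaged
over trees; OOB-Brier permutation importance is available behind a flag.
Rank ties break lexicographically so rankings are reproducible.  The
forest only *selects* the top-k (default 4) variables that define the
subgroup table; it is never the risk predictor.  Callers who need
independent observations reduce to one record per mother first.

## Problem sizes and numerical choices

The analysis drivers and synthetic checks run at 50,000 pregnancies per
stratum — about a seventh of the published cohort — which preserves every
rate and effect size while keeping each stage at seconds; acceptance-level
parameter recovery uses 50 replicates at that size.  Root-finding
tolerance 1e-13 on the intercept; IRLS tolerance 1e-10; LR/OR intervals on
the log scale; all percentages formatted at one decimal only at the
display layer.  Degenerate inputs have defined behaviour throughout: empty
tables, single-class outcomes, all-tied probabilities, constant outcomes
in the forest, unreachable incidence targets, and separated designs each
raise or return sentinels as documented above.

## Known limitations

Independence of exposures (margins only), no calendar time or
gestational-age process, no treatment (aspirin) effects, no missingness
mechanism, working-independence likelihood with post-hoc robust variance
rather than a random-effects model, and no external validation of the
fitted multiple models — the centile cutoffs and AUCs computed on
synthetic data characterise the procedure, not any real population.
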