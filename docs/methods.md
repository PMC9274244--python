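# Methods

## Overview

icees-lite models an open clinical–environmental data service at desk
scale. The pipeline has five stages: (1) ingest clinical records into one
canonical dataset; (2) link each geocoded patient to environmental exposure
sources; (3) coarsen everything into a de-identified feature table;
(4) select cohorts with rule-based inclusion criteria; (5) scan binned
features against a dichotomized health outcome with Pearson chi-square
tests under Bonferroni family-wise control, suppressing small cells in
every serialized output.

## Data model and ingest

The canonical dataset holds patients (birth date, sex, race, ethnicity,
optional geocode with timestamp, optional census block group) plus dated
condition, encounter, and procedure records. Two readers produce it: flat
CSVs and a deliberately minimal FHIR-R4-shaped bundle (Patient, Condition,
Encounter, Procedure; anything else is skipped and counted). Diagnosis and
procedure codes are normalized by removing dots and uppercasing before
prefix matching, so `E84.0` and `E840` both match prefix `E84`. Values
outside the sex/race/ethnicity enumerations coerce to
Unknown/Other/Missing with a logged warning rather than failing: the
validator (`validate_dataset`) is report-only by design so malformed inputs
can be loaded and audited.

## Exposure linkage

Point-source distances (CAFO, landfill) use the haversine great-circle
formula on a sphere of radius 6,371,000 m. Roadways are polylines of
straight segments; the patient-to-segment distance is computed in a local
equirectangular projection centered on the patient (closed-form
point-to-segment with clamping, vectorized over segments). At the scales
the bins care about (50 m roadway bins, 500 m site bins) the spherical and
planar approximations are accurate to well under 0.1%; the test suite
checks the segment distance against both a 10,001-point dense-sampling
oracle and an independent planar-geometry library. Exposure estimates are
computed once per patient per study period — no time weighting — and only
for patients with both a geopoint and a geocode timestamp; everyone else
gets an all-Missing exposure row. Residential density is a block-group
population lookup, not a point-in-polygon test.

## Binning and de-identification

Ages are completed years at day one of the study period, capped at 89, and
binned <5 / 5–17 / 18–44 / 45–64 / 65–89. Diagnosis features count
**distinct condition-record dates** per feature per patient within the
period (repeat same-day codes count once — an alternative counting rule can
be swapped in at one function) and are recoded 0 / 1 / >1. Roadway distance
bins are half-open low-inclusive at 50 m steps with a top bin ≥250 m; site
(CAFO/landfill) bins are <500 / 500–1,000 / 1,000–2,000 / 2,000–4,000 /
>4,000 m, where the `>4,000` label forces a strict bound so exactly 4,000 m
falls in the fourth bin. Density is rural (<2,500 persons per block group),
urban cluster (2,500–49,999), urbanized area (≥50,000). Every scheme is
total and exclusive over its domain, which the suite verifies by scanning.
Patient keys are salted SHA-256 hashes; the emitted table carries no raw
identifier, birth date, coordinate, or free text.

Which ICD code sets define each co-diagnosis feature is configuration, not
constant: the defaults in `DEFAULT_CODE_LISTS` are the obvious ICD-10-CM
chapters for each label and can be overridden per run. The respiratory
outcome's reason-code list defaults to prefix `J` (ICD-10 chapter X) and is
likewise configurable.

## Cohort rules

Inclusion criteria come in two groups — hospital/clinic locations visited,
and qualifying diagnoses/procedures — combined by AND (default) or OR.
AND is the default because location-only inclusion would be implausibly
broad; the combiner is configuration and logged. Age-at-event bounds are
strict upper bounds evaluated on exact day arithmetic (days / 365.25), so
sub-year bounds (echocardiogram before 6 months, tympanostomy before
1 year) behave correctly. The NICU criterion additionally requires
gestational age ≥ 35 weeks (term birth). The CF subcohort is: ≥1 in-period
condition record with code prefix E84, plus an active record (≥1 encounter
of any class in-period). The outcome counts in-period ED/inpatient
encounters with ≥1 respiratory reason code and is dichotomized 0 (better)
vs ≥1 (poor).

## Contingency analytics

Pearson X² = Σ(O−E)²/E with expected counts from margin products and **no
Yates continuity correction** — verified by exact agreement with the
published 2×2 sex statistic (0.9553). Zero-margin rows/columns are dropped
before df = (r′−1)(k′−1) is computed; this reproduces the published
degenerate case (single populated row → X² = 0, p = 1, rather than float
noise like 3.77e−16) and avoids 0/0. Patients Missing on a feature are
dropped for that feature only (pairwise deletion), which is why exposure
tables have N = 42 against N = 163 for co-diagnoses in the benchmark.
Bonferroni m is the number of features in the requested scan and is
recorded in the report. Suppression replaces any serialized count in
[1, threshold−1] (default threshold 10) with `ND`, and the row percentage
accompanying a suppressed count is suppressed with it; zeros display as 0.
Statistics (X², df, p, n) are aggregate quantities and are reported
unsuppressed.

Two p-value caveats in the benchmark source are documented rather than
matched: the middle-ear table prints P = 0.00169, which corresponds to
df = 1 although its own 3×2 shape gives df = 2 (p ≈ 0.00696 under the
convention every other co-diagnosis table follows); and the CAFO/landfill
printed p-values correspond to df = 5 rather than any zero-margin
convention on their 5×2 tables. The implementation follows the single
consistent convention throughout; all eleven printed chi-square statistics
and the seven internally consistent p-values reproduce exactly.

## Synthetic data generator

The generator emulates the benchmark study's conditions: one calendar year
(2020); 4,840 patients by default; demographic mix matching the observed
marginals (48.9% aged 65–89, 60.1% female, rural-heavy geography);
per-feature diagnosis level probabilities over {0, 1, >1} taken from the
observed cohort marginals; geocode coverage 27.42%; and a visit model in
which P(≥1 ED/inpatient respiratory visit) = 0.2256 at baseline and
positive counts are 1 + NegBin(mean 1.9, size 0.6), giving ≈77% zero mass
and a long tail with maxima in the 20s–30s. Configured effects are odds
ratios applied on the logit of the ≥1-visit probability given the patient's
≥1-diagnosis indicators, so all-OR-1 is an exact null for the downstream
scan. Block groups are a 12×12 grid partition of the bounding box
(central-North-Carolina-sized, 2° × 2°) with populations drawn 68% rural /
32% urban-cluster and no urbanized cells at defaults.

What it does **not** emulate: realistic ICD ontologies and code
co-occurrence, disease progression or seasonality, correlated demographics
(age × diagnosis), address clustering along roads, or multi-year histories.
Passing calibration tests therefore demonstrates statistical correctness of
the pipeline under a known model, not fidelity to any real population.

All randomness derives from a single `numpy.random.default_rng(seed)`
stream; a fixed seed reproduces datasets bit-for-bit, and the whole
simulate → build-table → analyze pipeline is byte-deterministic. The latent
draw (`draw_feature_levels`) is exposed separately so calibration studies
(2,000-replicate null family-wise error, 200-replicate power at OR = 10)
can run the exact generative model without materializing record lists;
those replicate counts keep the calibration suite in the seconds-to-a-
minute range at n = 500–2,000 per replicate.

## Benchmark fixture

The published CF-subcohort contingency counts are encoded as per-level
tuples and expanded programmatically into a 163-row feature table
(126 better / 37 poor; the first 23 and 19 rows of each group carry
exposure values, the rest are Missing). Because each published table
constrains only one feature × outcome joint, features can be assigned
independently within outcome groups and every cross-tabulation reproduces
its source table exactly. This is a reconstruction of published aggregates,
not patient data.

## Numerical and design choices

- Chi-square p-values come from `scipy.stats.chi2.sf`; the statistic itself
  is computed directly (the test suite cross-checks against
  `scipy.stats.chi2_contingency(correction=False)` and a loop-based
  textbook oracle to 1e−9).
- Distance bin boundary sides are fixed by the bin labels where the labels
  force a side, half-open low-inclusive otherwise, and are documented
  per-bin in the scheme objects.
- The ≥1-visit dichotomy, not the raw count, is the analysis outcome; the
  raw count is kept in the feature table for histograms.
- CSV floats are written with `repr` so read-back is exact; dataset
  equality is record equality, ignoring provenance.
- Degenerate inputs: all-zero contingency tables, negative counts/ages/
  distances, unknown source kinds, and criterion/kind field mismatches all
  raise typed errors (`DomainError`, `ConfigError`, `IntegrityError`).

## Known limitations

Straight-segment roadway geometry (no street networks); no air-pollutant
surfaces; no medications, labs, or procedure-based features in the feature
table; Fisher's exact test and multivariate models are out of scope — at
benchmark sample sizes several expected cells fall below 5, where the
chi-square approximation is rough; the suppression threshold protects
privacy but also hides exactly the cells that drive small-sample
instability.
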