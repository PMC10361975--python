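# Methods

## Study design being emulated

The pipeline models a two-institution diabetes-onset study: a municipal
health-checkup programme ("checkup", one examination per person per
year) and a university-hospital examination archive ("hospital",
several visits per year), observed 2014–2018.  Features from the
two-year observation window (2014–2015) predict whether a person meets
the diabetes diagnostic rule — HbA1c ≥ 6.5 % **and** fasting plasma
glucose (FPG) ≥ 126 mg/dl on the same occasion — at least once in
2016–2018.  Fifteen attributes are common to both sources (Age, Sex,
HbA1c, Hb, FPG, CBG, RBC, UG, UP, HDL-C, LDL-C, AST, γ-GT, Scr, Hct);
urinalysis (UP, UG) is semi-quantitative on the five-level scale
(−), (±), (+), (++), (+++).

## Synthetic cohort generator

Real checkup/hospital records of this kind are not publicly
distributable, so the generator produces cohorts with the statistical
structure the pipeline assumes:

* **Sizes and prevalence.**  Checkup: 1399 people, prevalence
  43/1399 ≈ 3.1 %; hospital: 1502 people, prevalence 209/1502 ≈ 13.9 %.
* **Class-conditional marginals.**  For the eleven features tabulated
  in the reference cohorts, the per-class means/SDs (quantitative) and
  category frequencies (Sex, UP) are used verbatim — e.g. checkup
  positives HbA1c 6.4 (0.4) vs negatives 5.8 (0.4); hospital positives
  HbA1c 7.0 (0.9).  FPG, CBG, Scr and UG are not tabulated there (they
  are removed by the missingness filter), so plausible clinical values
  were chosen once: e.g. checkup FPG 98 (12) / 135 (25) mg/dl for
  negatives/positives.
* **Visits.**  Checkup: exactly one visit per year.  Hospital: 1 +
  Poisson(2) visits per year (≥ 1, mean 3).
* **Missingness** is completely at random per value.  Rates are low
  (0.02–0.05) for routinely measured attributes and high for the
  attributes each institution rarely measures: checkup FPG 0.60 and
  UG 0.55; hospital CBG 0.85 and Scr 0.85.  The hospital rates must be
  well above 0.5 because yearly aggregation leaves a cell missing only
  when *all* visits are missing — with 1+Poisson(2) visits the expected
  yearly missingness is p·e^{−2(1−p)}, which is 0.63 at p = 0.85 but
  only 0.45 at p = 0.75.  This makes the 50 % filter remove exactly
  {FPG, UG} from the checkup data and exactly {CBG, Scr} from the
  hospital data, leaving the eleven-feature intersection (encoded
  d = 20) used by all analyses.
* **Outcome construction.**  Each person carries a latent class drawn
  from the prevalence.  In the outcome window, positives draw HbA1c and
  FPG from normals truncated at the diagnostic thresholds on *every*
  occasion (a persistently hyperglycaemic course), while negatives are
  capped so the two criteria never co-occur on one occasion.  Labelling
  is therefore recoverable from any co-observed occasion, which keeps
  label recovery at ~100 % under arbitrary missingness; with a single
  "diagnostic occasion" per positive, masking (checkup FPG is missing
  60 % of the time) would frequently hide it and corrupt the labels.
  Observation-window values are unconstrained class-conditional draws,
  so the prediction task is driven by the tabulated 2015 marginals, not
  by the outcome construction.
* Features are independent given the class; values are clipped at 0;
  age increments deterministically across years.  Correlated features,
  informative missingness and within-person autocorrelation outside the
  outcome window are deliberately not modelled.

## Cleaning pipeline

Aggregate (mean for quantitative, mode for qualitative, ties to the
most benign category) → keep samples observed at least once in both
2014 and 2015 → retain samples with HbA1c and FPG co-observed on ≥ 1
outcome-window occasion and label them by the diagnostic rule → remove
features with ≥ 50 % missing observation-window cells → remove samples
with < 50 % of the surviving cells → impute (column mean / mode) →
encode.  Sample sparsity is assessed before imputation (afterwards the
filter would be vacuous).  Encoding: one column per (feature, year) for
year-varying features, UP/UG as ordinal codes 0–4, Sex once (M=1, F=0),
Age once from the first observation year.

Two points are deliberate choices where the design was open.  The
diagnostic rule is checked on individual visits when visit-level data
are available and on yearly aggregates otherwise; occasion-level
co-occurrence is the default because the guideline pairs the two
measurements per examination.  Within an experiment replicate,
imputation statistics are fitted on the training subset only and
applied to the test split, so no test information leaks into training
(the standalone `preprocess` command, which produces a single dataset
rather than splits, imputes in place).

## Data-collaboration analysis

Worker i compresses its data with a private map
f_i : R^d → R^{l_i}, l_i < d.  `fit_intermediate_map` implements PCA
(centre on column means, keep the top-l principal directions) and
uncentred SVD; orientation is fixed by making the largest-magnitude
entry of each direction positive, so results are platform-independent.
Defaults: l_i = min(d−1, ⌈0.75·d⌉) (15 for d = 20), k = min_i l_i,
r = 1000 anchor rows.

**Worker-side standardisation.**  The `Worker` role standardises its
columns (with its own private means/SDs) before fitting the map.  The
shared features mix units whose raw variances span four orders of
magnitude (RBC ≈ 1200 vs HbA1c ≈ 0.16), so an unscaled variance-ranked
projection discards exactly the low-variance glycaemia and urinalysis
signals; measured on the synthetic cohorts it reduced quarter-subset
collaborative AUC from ≈ 0.96 to ≈ 0.6 and raised the map disagreement
on real samples to ~80 %.  Scaling statistics, like the map itself,
never leave the worker; anchors and test samples pass through the same
private pipeline.

**Anchors and alignment.**  Uniform anchors are drawn inside public
per-feature clinical reference ranges (never from any worker's private
minima/maxima); a SMOTE-style alternative interpolates random pairs of
rows of a supplied public reference table.  The master concatenates the
anchor intermediates, takes the top-k left singular vectors as the
common target Z, and solves each worker's least-squares problem by
`lstsq`; rank below k is rejected with a diagnostic.  The master API
accepts only intermediates and labels — raw matrices never cross the
worker boundary, which the test suite asserts at the interface level.

## Experiments

Per replicate, 99 test samples are drawn from the checkup institution;
the remainder is the training pool, subset to all/half/quarter (nested
draws).  Splits depend only on (master seed, replicate), so every mode,
subset and model sees identical test data — a paired design.  Models:
ℓ1-penalised logistic regression (liblinear, C = 1, on standardised
columns) and LightGBM with unrestricted depth, learning rate 0.1 and
100 estimators; no tuning.  Metrics: tie-averaged Mann–Whitney AUC and
recall/precision/F1 at probability threshold 0.5 (precision defined 0
when nothing is predicted positive), summarised as mean ± SD (ddof 0)
over 100 replicates.  Single-class test or training draws are redrawn
with a logged warning — with 3 % prevalence and 99-sample test splits
this occurs occasionally by construction.  The closed-form metric
implementations are cross-checked against the sklearn reference
implementations in the test suite.

"Bootstrap" here means repeated random re-selection of the 99-sample
test split (with the complement as the training pool), not resampling
training rows with replacement; the quarter subset is half of the half
subset.

## What the synthetic experiments do and do not show

On the synthetic cohorts the pipeline reproduces the *mechanics* of the
study — filters remove the expected features, labels are recovered,
the middle representation costs little relative to the individual
analysis (mean AUC gap ≈ −0.01), and the collaborative representation
tracks the pooled-training ceiling.  It does **not** reproduce the
*direction* of the collaboration benefit: with the tabulated
class-conditional marginals and independent features, the checkup task
is nearly separable (individual LR AUC ≈ 0.98 even at quarter size,
versus ≈ 0.86 reported for the real cohort), and the hospital cohort's
conflicting class structure (its Hb class gap is ≈ 0 where the
checkup's is +2.5 g/dl) makes *any* pooling — even with raw data and no
confidentiality transform — slightly harmful (measured pooled-raw AUC
0.944 vs individual 0.996 across quarter splits).  Real data are less
Gaussian, less separable and correlated, which is precisely the regime
where sample expansion pays off.  Passing tests therefore validate the
algorithmic correctness and reproducibility of the pipeline, not the
real-world benefit of collaboration.

## Numerical choices

* Orientation of all singular/principal vectors: largest-magnitude
  entry positive; ties default to the positive sign.
* Mode ties: smallest ordinal code (most benign category).
* Alignment least squares via `lstsq` (SVD-based); the oracle tests
  compare against an independent normal-equations solve at 1e−8.
* All seeds derive from one master seed through `SeedSequence`
  (stage keys for simulation/experiments, spawn keys per replicate);
  derived integer seeds stay below 2^31.
* Problem sizes in the test suite: full-scale cohorts (1399/1502) for
  the end-to-end properties, 100 replicates per experiment cell, and
  down-scaled cohorts (~160 samples) for unit-level checks.

## Known limitations

Independent features understate multicollinearity; MCAR missingness
understates informative measurement; the generator's outcome
construction guarantees label recoverability, which real registries do
not; only linear intermediate maps are supported; workers and master
run in one process (the confidentiality contract is an API-level
guarantee, not a cryptographic one).
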