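# Methods

This note documents the models and procedures implemented in
`oncofusion`, the assumptions behind them, the synthetic-cohort
generator's design, and the numerical and design choices made where the
problem left them open.

## Cohort data model

A cohort is a JSON array of per-patient objects merging all structured
modalities: demographics, pathology (pT/pN stage, grading, six binary
flags), a blood panel (value/unit/group per parameter), an ICD-10 code
list, CD3/CD8 densities (cells/mm²) at tumor center and invasion front,
and an event timeline in integer days since initial diagnosis (day 0).
Missing is JSON `null`; an absent key is equivalent.  When a death day is
present it defines the end of follow-up.  The machine-readable data
dictionary (`oncofusion/data/data_dictionary.json`) lists every field,
its type and its admissible values; validation rejects exactly those
domain violations and names the offending patient and field.  Real
cohorts of this kind ship modalities in separate per-modality tables; the
single-file layout here simply merges them per patient — the mapping is
one field group per source table.

## Multimodal patient vectors

Encoding rules per modality:

* **clinical/pathological** — binary flags → {0, 1, missing}; pT stage →
  pTis 0, pT1 1, pT2 2, pT3 3, pT4 4, pT4a 5, pT4b 6; pN stage → pN0 0,
  pN1 1, pN2(a/b/c) 2, pN3 3; grading → G1..G4 → 1..4; sex, smoking
  status and primary site → integer labels, expanded to full one-hot
  indicators at assembly.  The ordinal tables are configurable
  (`EncodingSchema`); the defaults are monotone in severity, and the
  pN a/b/c collapse keeps the scale consecutive.  No one-hot reference
  level is dropped: tree models are unaffected and cosine geometry stays
  symmetric across levels.
* **blood** — raw values of the hematology panel only (complete blood
  count); other groups (clinical chemistry, coagulation) are excluded.
  Panel membership is configurable.
* **ICD codes** — bag-of-words over the literal first four characters of
  each code ("C32.0" → "C32."), i.e. the category level; prefixes carried
  by fewer than 3 patients are discarded; the vocabulary is sorted
  lexicographically and per-patient vectors hold presence counts.
* **TMA** — the four densities as numerics.

Blocks concatenate in fixed order (clinical_pathological, blood, icd,
tma).  Imputation is per-feature mode (binary/categorical; ties resolve
to the lowest label) or mean (ordinal/numeric); ordinal and numeric
columns are z-scored; a zero-variance column is centered and left at 0.
A patient's **completeness flag** is decided before any imputation; one
deliberate exception: a missing grading does not make a patient
incomplete, because HPV-associated carcinomas are structurally ungraded
rather than unmeasured.  For visualization and GA splitting the
preprocessing statistics are fitted on the whole cohort (the natural
reading for a cohort-level embedding); inside model evaluation they are
fitted on the training patients only — including the ICD vocabulary — to
exclude any leakage.  A leakage audit test verifies that perturbing a
test patient changes no other patient's prediction.

2-D projection uses UMAP with library-default neighbors/min-dist (capped
at n−1 neighbors for small cohorts), a fixed random state derived from
the seed, and both axes min-max rescaled to [0, 1].

## Genetic-algorithm dataset splitting

A split genome is a binary mask over the eligible (complete-vector)
patients with popcount fixed at N = round(test_fraction × n_eligible);
ineligible patients always train.  Fitness (maximized):

* in-distribution: Σ_i (1 − cos(x_i, x_i,nn)) over test points, nearest
  neighbor among the *other test points*;
* out-of-distribution: Σ_{i<j} (1 − cos(x_i, x_j)) over test pairs;
* both minus α·Σ_k |d_k − d_k,all| over C = 2 target classes
  (recurrence, survival status), with per-class fractions computed over
  labeled patients only (missing outcomes drop out of the penalty but
  stay splittable).

Defaults chosen where the problem statement is silent: α_in = N and
α_out = N(N−1)/2, scaling the penalty to the magnitude of the respective
distance sum so balance competes meaningfully in both modes; tournament
size 3, elitism 1% of the population, one-point crossover at rate 0.9,
inversion (segment-reversal) mutation at rate 1/n per individual, and
repair of crossover children to exactly N bits by random flips.
Inversion preserves popcount by construction.  Zero-norm vectors take
cosine distance 1 to everything (logged convention); nearest-neighbor
value ties are inconsequential to the sum.  The reference configuration
(population 10,000, stop after 50 stagnant generations) is the package
default; tests and the bundled benchmarks use populations of 150–300
with stagnation 15–40, which already reach the enumeration optimum on
every small instance tried and keep full runs in minutes.

An exhaustive oracle (`exhaustive_split_oracle`) enumerates all C(n, N)
masks (capped at 10⁶) with lexicographically-smallest tie-break, serving
as the independent optimality check.

One property deserves a note: the mean *per-point nearest-train*
distance of the in-distribution test set is typically **larger** than
the out-mode's, not smaller — the coverage objective favors locally
isolated points, and the much larger α_out makes the out-mode more
balance-constrained.  The intended contrast (in-distribution test
resembles the training distribution; out-distribution loads on extremes)
is real and is asserted on the mean cosine distance to the training
centroid, where it holds robustly, and behaviorally in the AUC ordering
benchmark.

## Outcome prediction

Labels at day resolution, 3 years ≡ 1095 days (no leap handling):

* recurrence — positive: recurrence ≤ 1095 d; negative: no recurrence,
  death absent or > 1095 d, follow-up ≥ 1095 d; everything else excluded
  with a reason (insufficient follow-up, early non-recurrence death, or
  recurrence after 3 years — the last because it satisfies neither class
  definition).
* survival status — positive: deceased with tumor-specific or unknown
  cause; negative: alive; non-tumor-specific deaths excluded.

SMOTE is implemented in-package (imbalanced-learn is not a dependency):
synthetic minority samples interpolate between a random minority point
and one of its k = 5 nearest minority neighbors until classes are equal;
k shrinks automatically (with a warning) when the minority is smaller
than k + 1.  The classifier is a Random Forest (500 trees, √p features,
unlimited depth by default — the benchmarks use 150 trees, which tracks
the 500-tree results closely at a third of the cost).  Each split × task
cell is evaluated five times with derived seeds; ROC curves are averaged
by TPR interpolation on a 101-point FPR grid.  The held-out site is a
parameter (`site_holdout_split(cohort, site)`); examples use the
oropharynx.

## Attention MIL

A bag is one patient's instance embeddings with per-instance source tags
(WSI; TMA stains CD163, CD3, CD56, CD68, CD8, HE, MHC1, PDL1; 32 tiles
per core, two cores per stain by default, so eight stains give 512 TMA
instances).  Bag-level 3-year survival labels: death ≤ 1095 d →
deceased; death > 1095 d → force-labeled alive (the event is no longer
attributable to the 3-year window); alive with ≥ 1095 d follow-up →
alive; alive with less → excluded.

The network is two-layer gated attention: per instance h,
a ∝ softmax(wᵀ(tanh(Vh) ⊙ σ(Uh))) with hidden size 32; bag
representation z = Σ a_i h_i; linear head → sigmoid bag score (softmax
for the multi-class tumor-localization option).  The loss is bag
cross-entropy plus `clustering_loss_weight` × an instance term: the k
most-attended instances are pseudo-labeled with the bag label and the k
least-attended with 0 (k = 8), and a separate linear instance classifier
is fitted to them by binary cross-entropy — a deliberate simplification
of clustering-constrained attention frameworks whose instance loss
shapes a trainable encoder; here the embeddings are fixed inputs, so the
term regularizes attention's pseudo-label consistency only and the
weight-0 ablation reduces exactly to plain attention MIL.  Gradients are
derived analytically (softmax-attention backprop) and optimized with
Adam (lr 3 × 10⁻³), one bag per step, 60 epochs by default.

Two robustness measures matter at this scale.  First, `attend` sorts
instances into a canonical order before the forward pass and unsorts the
weights, making attention *bit-exactly* permutation-equivariant (naive
summation order breaks exact equality).  Second, `restarts = 3` (5 in
the combined-source benchmark) trains independently initialized networks
and averages their scores and attention: single runs occasionally latch
onto one of several signal directions or collapse on very small bag
sets, while ensemble members tend to cover the directions jointly.

## Survival statistics

`km_estimate` wraps the standard product-limit estimator (computed via
lifelines) into a step-function container with at-risk counts, censoring
marks and a Greenwood-variance 95% band on the log scale; deaths precede
censorings at tied times (the standard convention).  `survival_at` is a
right-continuous lookup, carrying the last value forward beyond the
observed range.  `mwu_test` computes U with midranks; for total n ≤ 12
the two-sided p-value is exact — P(|U − μ| ≥ |U_obs − μ|) over all
C(n, n_a) group assignments, which handles ties — and beyond that the
tie-corrected normal approximation with continuity correction is used.
The exact and asymptotic branches agree within 0.02 at the boundary.

## The synthetic cohort: what it emulates, and what it does not

The generator targets the printed marginals of a real single-center
head-and-neck cohort — 80% male, 72% ever-smokers, median age 61 (SD 11,
a typical spread for this disease), five primary sites at plausible
frequencies — plus configurable missingness (mostly block-structured:
a whole blood panel or TMA core absent; ~70% of patients end up
complete) and a small per-site ICD vocabulary with both frequent and
below-support codes.

Outcomes follow a logistic model whose signal is deliberately spread
over four standardized modality axes — tumor severity (stage), blood
anomaly, comorbidity burden (ICD), immune infiltration (TMA, protective)
— each with log-odds slope 0.9 around base rates of 0.25 (recurrence)
and 0.30 (death).  With all slopes zero the endpoints are exact
Bernoulli draws at the base rates (the closed-form check).  Event days
follow discrete geometric hazards (means 400/600 d); follow-up ends at
death or a uniform censoring time up to ~14 years.

Two structural features give the cohort the difficulty gradient the
split benchmarks probe, and both are deliberate departures from a single
global logistic law:

* **Atypicality attenuation.** The modality signal (not the base rate)
  is divided by 1 + 2.0·max(0, z̄² − 0.8), where z̄² is the patient's
  mean squared standardized blood/TMA value.  Patients with extreme
  observed presentations — whatever the cause — are therefore less
  predictable from routine features.  Without this, a single global
  monotone model makes distribution extremes the *easiest* patients to
  rank (their log-odds spread is widest), inverting the expected
  in- vs out-of-distribution ordering.  The linear form with onset just
  below the bulk mean (z̄² ≈ 1) was selected because it attenuates the
  moderately extreme patients an out-of-distribution split actually
  picks; tail-only (quadratic) or stronger global variants either miss
  those patients or crush the overall signal.
* **Oropharynx concept shift.** For oropharyngeal tumors the stage,
  blood and ICD slopes are damped by (1 − 0.6·site_confounding) while
  the immune-density slope is kept — a caricature of the distinct,
  largely HPV-driven biology of that site — and `site_confounding` also
  shifts per-site feature means and outcome offsets.  This is what makes
  a site-holdout split genuinely hardest rather than just differently
  sampled.

For MIL, `SyntheticEmbeddingSource` emits isotropic Gaussian instance
embeddings (d = 64); positive patients get a fraction (10–15%) of
instances in designated sources shifted 4σ along a fixed per-source unit
direction.  The shift must clear the extreme-value projection of bag
noise — with ~50 instances per bag the maximum noise projection onto any
direction is ≈ 2.2–3σ, so a 2σ "signal" is statistically invisible to an
attention model; 4σ makes bags separable by construction.  The
`per_patient_sources` override plants complementary signals (half the
positives detectable only via WSI, half only via one TMA stain), the
regime in which combined-source bags must beat either source alone.

What the generator does **not** emulate: realistic joint feature
distributions or ICD epidemiology, pixel-level images or free-text
reports, treatment effects, competing risks, or calendar-time artifacts.
Passing benchmarks therefore demonstrate that the pipeline's machinery
recovers structure that is present by construction — they do not certify
effect sizes or AUC levels on real cohorts.

## Benchmark problem sizes

The bundled experiments (`oncofusion.experiments`, also driven by
`scripts/acceptance.py`) use cohorts of 200 patients (balance, outlier
capture; the outlier cohort is generated without missingness so every
planted patient is eligible for the test set) and 600 patients (split
ordering, fusion), 10 replicate seeds per experiment, 5 forest repeats
per cell, 150-tree forests, GA populations of 150–300, and MIL sets of
200–300 bags of 32–48 instances.  These sizes keep a full benchmark run
around ten minutes on a single CPU while leaving every planted effect
measurable with margin; all sub-seeds derive from one master seed.

## Known limitations

* The GA's reference population size (10,000) is impractical to exercise
  in routine testing; optimality is instead verified against exhaustive
  enumeration on small instances.
* The MIL trainer is plain numpy: adequate for hundreds of bags of
  hundreds of instances, not for gigapixel-scale workloads, and it
  consumes precomputed embeddings only (no encoder training).
* The exact rank-sum branch enumerates assignments and is limited to
  total n ≤ 12 by design.
* Split-regime AUC comparisons on ~80-patient test sets carry sampling
  noise of several AUC points; the benchmarks therefore assert orderings
  over replicate majorities, not point values.
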