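# Methods

`lung_turnover` implements an island-biogeography analysis of longitudinal
lung-infection microbiota: per-patient taxa-by-visit relative-abundance
series are partitioned into chronic and intermittent colonizers, temporal
turnover is quantified with species–time relationships, and pairwise
community turnover is attributed to ecological processes with a Raup–Crick
null model.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Data model and inclusion

A patient's series is a taxa × sample matrix of relative abundances; every
sample column sums to 1 (tolerance 1e−9) and the time axis is integer days
since that patient's first sample.  Counts are normalized on load; taxa a
patient never carries are dropped from that patient's series; two samples of
one patient on the same day are rejected (the species–time axis needs
strictly positive intervals) unless `merge_same_day` unions them with
abundance averaging.  Sputum and cough-swab samples are treated identically.
Detection means relative abundance strictly above `detection_min`
(default 0: presence in the table).

Patients enter the analysis only with at least `min_samples` = 6 samples
and a sampling span of at least `min_duration_days` = 731 days (i.e.
strictly beyond two years): persistence classification from fewer samples is
unreliable, and a span of exactly 730 days is excluded.

## Chronic/intermittent partition and persistence–abundance relationships

Persistence of a taxon is the percentage of the patient's samples it is
detected in.  Following the modified Leeds rule, a taxon is a *chronic*
colonizer of that patient iff persistence is strictly greater than
`persistence_threshold_pct` = 50; exactly 50% is intermittent.  The
persistence–abundance relationship (PAR) is an ordinary least-squares fit of
persistence (%) on log10 mean relative abundance, the mean being taken over
only the samples in which the taxon was detected.  The log10 transform is
the package default (`par_abundance_transform`) because abundances span
several decades; `identity` is available.  The regression direction is
persistence-on-abundance; R² is direction-invariant, the slope is reported
for the stated direction.

## Species–time relationships

The STR models observed richness against observation span as S = c·T^w; w
(the temporal scaling exponent) measures turnover.  The default `pairwise`
construction slides a two-sample window along adjacent visits: S is the
richness of the first sample plus the taxa newly observed in the second
(equivalently the cardinality of the union of the two presence sets), and T
is the elapsed days between the two visits.  Repeated immigration and
extinction of one taxon therefore counts every time it happens.  A
classical variable-length `window` mode (union over samples i..i+L−1, T the
day span, all L = 2..N) is provided for sensitivity analysis.  T is actual
elapsed days, not sample index, because visit intervals are irregular.

The fit is OLS of log10 S on log10 T (w = slope, c = 10^intercept) with R²,
F = (R²/(1−R²))(n−2) and p from F(1, n−2).  Points with S = 0 (possible in a
sparse intermittent subset) are dropped with a logged warning — the log is
undefined there and such windows carry no turnover signal; at least three
usable points are required.  Group fits (whole microbiota / chronic /
intermittent) evaluate presence on the group-subset matrix, which is *not*
renormalized (downstream use is presence/absence only).

## Raup–Crick similarity and process attribution

For every unordered within-patient sample pair the observed number of
shared taxa is compared with a Monte-Carlo null (default `rc_iterations` =
1000) in which two communities of the same richnesses are assembled from
the regional species pool — the union of all taxa detected in any sample of
any patient, restricted per analysis group to taxa holding that status in
at least one patient.  Null assembly draws taxa without replacement with
probability proportional to occurrence frequency (`rc_weighting` =
`occurrence`; `uniform` is provided as a sensitivity knob because some
legacy implementations weight uniformly).  With p = (#{null < observed} +
½·#{null = observed}) / iterations — ties split half-weight, the standard
probability-based construction — the similarity index is S_RC = 2p − 1 in
[−1, 1], oriented as similarity (+1 = more similar than chance).

Process attribution is boundary-inclusive at `rc_threshold` = 0.95:
S_RC ≥ 0.95 → homogenizing dispersal, S_RC ≤ −0.95 → dispersal limitation,
otherwise drift; the thresholds approximate a two-sided 5% test.
Speciation cannot be separated by a presence/absence index at these time
scales and is not scored.

Implementation: weighted sampling without replacement uses the Gumbel
top-k construction (descending log-weight + Gumbel noise reproduces
successive draws proportional to remaining weight).  Within
`raup_crick_matrix`, two ranking matrices are drawn once per
(patient, group) from a substream derived by sha256 from the master seed,
and each sorted richness combination (n_a, n_b) reads a nested prefix of
those rankings, cached.  This keeps exact Plackett–Luce marginals while
making results deterministic, symmetric in the pair, independent of
evaluation order, and fast enough for cohort-scale runs.  Samples with no
detected taxa in the chosen group are skipped and logged.

An exact oracle (`exact_null_srcs`) backs the Monte-Carlo estimator in the
tests: for uniform weights the null shared count is
Hypergeometric(pool, n_a, n_b) in closed form for any pool size; for
weighted pools of at most 12 taxa the unordered-subset probabilities of
successive weighted sampling are enumerated by dynamic programming over
bitmasks, and larger weighted pools are refused as combinatorial.

## Cohort statistics

Group comparisons use the tie-corrected Kruskal–Wallis H (p from χ² with
k−1 df) with Dunn's post-hoc z on pooled tie-corrected ranks (adjustment
`bonferroni` by default; `holm`/`none` available — Bonferroni is the
conservative choice where the source analyses do not state one).
Regressions are simple OLS with the F/R² identity above; p-values are
reported exactly with no cross-analysis multiplicity correction.  Cohort
summaries report the mean ± sample standard deviation (n−1 denominator;
reported SD magnitudes are far too large to be standard errors); a
singleton group reports SD 0 with a logged warning.  The lung-function
analysis regresses per-patient whole-microbiota homogenizing-dispersal and
drift percentages on per-patient mean %FEV1, per cohort.  The
paediatric-vs-adult lung-function comparison uses per-patient mean %FEV1
values (one value per patient), matching the axis convention of the
reference analysis.

## Synthetic cohorts

The generator exists so every stage is testable without sequencing data and
so parameter recovery can be asserted.  Defaults mirror the study
conditions: 15 patients per cohort, 6–20 samples per patient with the last
visit at 785–1166 days (first at day 0, interior days uniform without
duplication), a global pool of 600 taxa with a 12% resident fraction,
resident detection propensity 0.70–0.98 and transient 0.02–0.30, and
%FEV1 ~ Normal(90.5, 14.5) (paediatric-like) or Normal(75.9, 18.9)
(adult-like) truncated positive, with exacerbation counts Poisson with
log-rate 3.0 − 0.03·%FEV1 (the negative link reproduces the inverse
exacerbation–lung-function relationship).  Latent log10 abundance is
`abundance_base` + `abundance_coupling`·logit(propensity) + noise
(defaults −2.0, 0.5, 0.3), so commonness and abundance are coupled and PARs
are positive by construction; detected entries get lognormal per-sample
noise (σ = 1.0 in natural log) and columns are normalized.

Two overlap regimes set how presence varies between visits:

* **homogenizing** — each patient draws a personal pool (120–260 of the
  global 600), designates residents, and fixes a presence template
  (Bernoulli in the class propensity); every sample re-expresses the
  template with independent flip noise (`flip_noise` = 0.05).  Template
  members persist at ≈ 1 − flip_noise, so their chronic classification
  follows a Binomial(n, 1−e) tail; within-patient pairs share almost
  everything and classify as homogenizing dispersal against the
  cohort-level pool.
* **drift** — every sample is an independent weighted lottery from the
  shared global pool, i.e. the same kind of draw the Raup–Crick null
  performs: the community is the top-n of Gumbel-perturbed log-propensities
  with propensity = detection_prob^`assembly_evenness` (default 0.7) and
  per-sample richness uniform on `sample_richness` (default the
  `per_patient_pool` range, 120–260).  Because generation and null share
  the assembly mechanism, most pairs fall inside the ±0.95 band and drift
  is the modal attribution.  Residents are captured by most lotteries and
  realize > 50% median persistence; note the realized persistence is the
  lottery inclusion probability, a compressed transform of the nominal
  propensity, not the propensity itself.  Temporal memory enters through an
  AR(1) Gaussian copula on the Gumbel noise with lag correlation
  exp(−Δt/τ), τ = `correlation_time_days` = 25 days (the order of a short
  inter-visit interval): nearby visits share composition, so the union of
  presence sets grows with elapsed time and w is positive — substantially
  more for the churning transient fraction than for the stably captured
  residents, reproducing the intermittent-driven turnover structure.  τ = 0
  gives fully independent samples (w ≈ 0 for every group).

  The evenness exponent and the decoupled per-sample richness are the
  resolution of a real tension: an occurrence-weighted
  without-replacement null *cannot* be exactly self-consistent with any
  heterogeneous-prevalence community (inclusion probabilities flatten
  under reweighting), so strongly contrasted Bernoulli presence would be
  classified homogenizing nearly everywhere.  The lottery with softened
  propensities keeps distinct resident/transient classes while staying
  close enough to its own null that drift dominates, which is the regime's
  purpose.

An optional knob `fev1_process_coupling` (default 0, i.e. clinical
covariates independent of the microbiota) multiplies a patient's τ by
exp(coupling·(cohort mean %FEV1 − patient %FEV1)/cohort SD): with positive
coupling, worse lung function means longer compositional memory and hence
more homogenizing-dispersal calls, which exercises the
process-vs-lung-function regression recovery.

What the generator does **not** emulate: sequencing-read noise, chimeras or
contamination, compositional count noise beyond lognormal-then-normalize,
taxonomic structure, antibiotic perturbations, or secular trends in
richness.  Passing recovery tests on these cohorts therefore shows that the
pipeline measures what each regime encodes — not that real sputum series
satisfy the regimes' assumptions.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all data at run time.
Property rates are computed on 100 synthetic patients per regime with 1000
Raup–Crick randomizations per pair; oracle agreement uses 50 random uniform
pools (≤ 12 taxa) at 10^5 iterations; regression-null calibration uses 60
scaled-down replicate cohorts; the determinism check runs a 4-patient
cohort through the full pipeline twice and compares outputs byte for byte
(the JSON summary is compared with its run-specific output path normalized
out).  All randomness flows from one user seed through
`numpy.random.SeedSequence` spawning plus sha256-derived substream ids, so
every result is reproducible and order-independent; TSV outputs are written
with fixed 10-significant-digit formatting to make reruns byte-identical.

## Known limitations

* Persistence from 6–20 samples is coarse (steps of 5–17 percentage
  points); taxa near the 50% boundary classify unstably between reruns of
  the sampling process (not of the pipeline, which is deterministic).
* The pairwise STR uses adjacent windows only by default; estimates of w
  from few visits are noisy, and windows longer than two samples are a
  sensitivity option rather than a second estimator of record.
* The Raup–Crick index conditions on richness and presence only; abundance
  shifts without membership change are invisible to it.
* Group-level regional pools depend on the Leeds partition and therefore on
  `persistence_threshold_pct` and `detection_min`.
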