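# Methods

## Scope

`ctcsurv` analyses cohorts of early breast cancer patients with circulating
(CTC) and disseminated (DTC) tumor cell counts, two censored endpoints —
distant recurrence-free survival (DRFS) and breast cancer-specific survival
(BCSS) — and the clinicopathologic covariates age, overall pathologic
stage, tumor grade and receptor subtype. Its core is a Monte-Carlo
cross-validated search for the most prognostic dichotomising marker
threshold per histologic subtype (ILC vs IDC), followed by dichotomised and
four-group survival modelling. Because patient-level data of this kind are
rarely public, the package ships a synthetic-cohort generator that encodes
the statistical structure such analyses assume; everything downstream is
validated against cohorts whose truth is known by construction.

## Synthetic cohort model

One patient row carries histology, age, receptor subtype, stage, grade,
treatment strategy (primary surgery vs neoadjuvant), enumeration method
(IE/FC vs CellSearch), CTC and DTC counts per mL, and (time, event) pairs
for DRFS and BCSS.

**Marker counts.** Counts are zero-inflated log-normal per (marker,
histology, treatment) stratum: zero with probability π, otherwise
LogNormal(μ, σ). The overall mean is (1−π)·exp(μ+σ²/2); `MarkerModel.from_mean`
solves μ for a target mean. Rationale: assay positivity is well below 100%
(an atom at zero) and positive counts are heavily right-skewed (such data
are conventionally displayed after log10(x+1) transformation). Values are
rounded to `marker_decimals` (default 2, i.e. 0.01 cells/mL — the precision
at which such thresholds are reported). No CTC–DTC correlation is imposed.

**Covariates.** Age is normal per histology (clipped to [18, 100]);
subtype, stage and grade are categorical per histology. Covariates are
independent given histology, because only marginal per-histology
distributions are typically available to calibrate against. This means the
generator does *not* reproduce real-world covariate–marker confounding; a
pass of the covariate-adjustment tests shows the adjustment machinery is
correct, not that adjustment in real data would be small.

**Survival.** Event times are exponential with a per-endpoint baseline rate
(per year); censoring times are uniform on a per-endpoint window
[censor_low, censor_high], event = (event time ≤ censoring time). An
optional *planted cutpoint* multiplies the hazard by a configurable ratio
for patients whose marker strictly exceeds a threshold, on the listed
endpoints — the ground truth for recovery experiments. The exponential/
uniform choice keeps log-rank and Cox behaviour analytically predictable;
it does not model non-proportional hazards or late-recurrence dynamics.

**Defaults** (`default_study_spec`): 382 patients, P(ILC) = 83/382,
P(neoadjuvant) = 98/382, all IE/FC; subtype/stage/grade probabilities from
a 382-patient reference cohort's non-missing margins; age means 54 (ILC)
and 50 (IDC), SD 11; stratum CTC means 2.11/0.71 (ILC/IDC primary surgery)
and 0.89/1.06 (neoadjuvant), DTC means 21/16 and 11.1/19.6 cells/mL, with
π = 0.35 (CTC), 0.30 (DTC) and σ = 1.2 (CTC), 1.5 (DTC): the printed means
only pin one moment per stratum, so π and σ are free knobs chosen to give
realistic positivity and skew (they reproduce high-marker rates near the
reference analysis's 50.8%/37.2% CTC-high fractions at its thresholds);
DRFS/BCSS baseline rates 0.02/0.012 per year with censoring windows [2, 18]
and [6, 20] years, giving reverse-Kaplan–Meier median follow-up ≈10 and
≈13 years and event fractions under 20%; missingness rates matched to the
reference tables' Unknown rows (subtype 3.7%, stage 3.9%, grade 16%, DTC
5%). No cutpoint is planted by default — the default cohort is null with
respect to marker–outcome association.

**Seeding.** One master seed; `numpy.random.SeedSequence.spawn` derives one
substream per column group in a fixed, append-only order, so adding a new
column group cannot perturb existing columns. Identical (spec, seed) pairs
generate byte-identical tables.

## Statistical primitives

* **Kaplan–Meier**: product-limit with tied events grouped; median = first
  event time with S ≤ 0.5. Median follow-up uses the reverse estimator
  (censoring as the event).
* **Log-rank (2 groups)**: Σ(O−E) with the grouped hypergeometric variance
  at each distinct event time, χ²₁ reference; zero-variance times
  contribute nothing; zero events overall → statistic 0, p = 1, flagged
  degenerate. `logrank_grid` evaluates the same test simultaneously for
  every threshold of a dichotomisation grid (membership matrix + suffix
  sums), which is what makes 1000-iteration × ~100-candidate searches
  cheap. Four-level groupings in the pipeline use lifelines'
  k-sample log-rank.
* **Welch t**: unequal-variance statistic with Welch–Satterthwaite df;
  identical inputs give p = 1.
* **Fisher exact**: two-sided by the probability-mass rule (sum of tables
  with margin-conditional probability ≤ observed, 1e-7 relative slack for
  float ties). Tables with a 2-row or 2-column layout — every table this
  pipeline produces — are enumerated exactly; anything larger falls back to
  a seeded Monte-Carlo estimate (1e5 draws of the fixed-margins table
  distribution). The probability-mass rule matches the convention of
  standard statistical software.
* **Logit combination** (Mudholkar–George): G = −Σ log(pᵢ/(1−pᵢ)) referred
  to C·t with ν = 5k+4 and C = √(kπ²(5k+2)/(3ν)); upper-tail probability
  returned. Inputs are clipped to [1e-15, 1−1e-15] to keep the logit
  finite (a float-underflow guard with no effect above machine precision).
* **Cox proportional hazards**: lifelines `CoxPHFitter` (Efron ties,
  Newton–Raphson at 1e-9 precision), Wald confidence intervals and
  p-values. Monotone likelihood (perfect separation) — including fits that
  "converge" to |β| > 50 — raises a flagged error rather than returning a
  silent estimate. Categorical covariates enter as indicator contrasts with
  stage 1, grade 1 and HR+HER2− as reference levels; model rows are
  complete cases.

## The cutpoint search

Configuration (`MccvConfig`): 1000 iterations, train fraction 0.5,
percentile band [20, 80], endpoint policy `combine_logit` (reduce the DRFS
and BCSS log-rank p-values at a threshold to one number via the k = 2 logit
combination; `drfs_only`/`bcss_only` select a single endpoint), minimum
group size 5, one seed.

Design choices where the procedure is genuinely underdetermined:

* **Global candidate grid.** Candidates are distinct observed values whose
  percentile rank (100·#{x ≤ v}/n) lies inside the band, computed on the
  *full* subset rather than per training half. Thresholds selected in
  different iterations are thereby identical values that can be grouped
  and combined; per-half grids would make "combine the test p-values per
  threshold" ill-defined. With ≥20% of the subset on each side of every
  candidate, both dichotomised groups are always populated.
* **Strict-greater dichotomisation** ("high" ⇔ value > τ), so a threshold
  equal to an observed value puts that value in the low group.
* **Ties** in p-value minimisation break toward the smaller threshold (the
  more sensitive classification), both per-iteration and at the final
  combined-p selection.
* **Unusable iterations** (selected split leaves a group under
  `min_group_size` in either half) are excluded from the combination
  rather than imputed p = 1, which would bias the combined p.
* **Splits** are simple random halves without stratification by event
  status; `min_group_size` guards the degenerate ones.

**Known limitation — dependence across iterations.** The logit reference
distribution assumes independent p-values. Test halves of different
iterations share about half their subjects, so the per-iteration test
p-values at a fixed threshold are strongly positively correlated, and a
combination of many of them is over-dispersed relative to the nominal
scaled-t: markedly too many extreme combined p-values in both tails even
under the null. The package therefore treats the combined p as a *ranking
score* for choosing among thresholds, not as a calibrated significance
level; the calibration experiment (below) verifies the machinery in the
one regime where the independence assumption holds exactly. Selection of
the minimum combined p additionally inflates significance (no minimum-p
correction is applied), which is why the chosen threshold's combined p is
stochastically smaller than uniform even on null cohorts.

## Pipeline conventions

* Exclusions: records missing histology or CTC count are dropped, with
  per-reason counts reported; retained records partition exactly by
  enumeration method × treatment strategy.
* Count comparisons report raw-scale group means with a Welch p (so means
  match what tables print), and a covariate-adjusted p from OLS of
  log10(x+1)-transformed counts on histology + age + grade + stage +
  subtype, complete cases; single-level covariates are dropped with a
  warning. A count GLM would be a reasonable alternative family; the
  linear-on-transformed-scale model was chosen for transparency.
* Characteristics tables: mean (SD) with Welch p for age; n (%) over
  non-missing denominators with Fisher p for categoricals; Unknown counts
  on separate rows; percentages print with one decimal below 10%.
* Dichotomised and four-group survival: per-level Kaplan–Meier, log-rank
  across levels, univariate and multivariate Cox with low (or low/low) as
  reference; levels with zero events are reported non-estimable and
  excluded from the fit; cutpoint optimisation and survival modelling run
  on the primary-surgery cohort only (the neoadjuvant cohort gets
  characteristics and count comparisons — with no count signal there,
  outcome modelling by histology is not attempted).
* Reports are JSON with sorted keys and 6-significant-digit floats; every
  artifact embeds package version, config hash and master seed, making
  identical runs byte-identical.

## Validation experiments

* **Planted-cutpoint recovery** (`experiments.recovery_experiment`): 400
  patients, hazard ratio 4 on DRFS planted at the marker's theoretical
  median, DRFS baseline rate 0.05/year (≈40% events — a deliberately
  well-powered regime for an oracle), 200 iterations, 20 seeded runs. The
  scenario sets marker resolution to 0.1 cells/mL so that adjacent
  candidate thresholds describe materially different dichotomisations; at
  0.01 resolution the grid near the median is so dense that "one grid
  step" separates splits differing by a single patient, and no estimator
  could be expected to resolve it. Success = chosen threshold within one
  grid step of the planted value; the observed rate is ≥ 90%.
* **Null calibration** (`experiments.calibration_experiment`): 200
  replicate null cohorts; in each, one random split, the log-rank p at the
  fixed median threshold on each of the two *disjoint* halves, combined
  with the k = 2 logit method. Disjoint subject sets give independent
  p-values, so the combined p must be Uniform(0,1); a Kolmogorov–Smirnov
  test checks it. This is deliberately not run over many overlapping
  iterations, for the dependence reason documented above.
* **Selection effect** (`experiments.selection_effect_experiment`): the
  chosen threshold's combined p on null cohorts, demonstrating the
  anticonservatism of minimum-p selection.

Problem sizes in the test suite (exhaustive log-rank to n = 8, 252-split
exhaustive search agreement at n = 10, Cox recovery at n = 2000, 200-
replicate calibration) were chosen as the smallest sizes at which each
check is statistically meaningful; they keep the full suite around a
minute on one CPU.

## What passing tests do and do not show

The generator reproduces the *marginal* structure it was given: stratum
means, zero fractions, covariate mixes, follow-up and event rates, and
planted hazard steps. It omits covariate–marker confounding, CTC–DTC
correlation, assay measurement error, inter-assay (IE/FC vs CellSearch)
conversion, non-proportional hazards and competing risks. Green tests
certify the *procedure* — bookkeeping, statistics, search, reporting — on
data satisfying the model's assumptions; they do not certify that any
particular published threshold is biologically optimal, nor that the
combined p of a selected threshold is a calibrated error rate.
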