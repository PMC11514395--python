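# Methods

## Scope and model structure

The package implements a two-stage cost-effectiveness comparison of
pharmacogenetic (PGx) panel-guided antidepressant prescribing versus
standard of care (SoC) in adults with moderate–severe major depressive
disorder: a 6-week decision tree for the acute episode, then a lifetime
(age 48–81) Markov cohort model in 3-month cycles. All costs are Qatari
Riyal at 2024 prices (3.64 QAR = 1 USD); outcomes are response
probabilities (short term) and discounted life-years and QALYs (long
term). Analysis is cohort-level throughout; there is no patient-level
heterogeneity beyond the gene × metabolizer-class × carrier strata.

### Decision tree

Each arm's cohort is partitioned by gene (a configurable prescription-
share weight, default 0.5/0.5, attributes each patient to exactly one gene
sub-model), metabolizer class and carrier status. Within a cell the leaf
grammar is: response → side effects → relapse; relapse leads to a
disposition among {switch, observe, discontinue, suicide attempt}, no
response among {switch, titrate, observe, discontinue, suicide attempt};
an attempt resolves to death or survival. That yields 18 leaves per cell,
and leaf probabilities sum to one by construction (asserted to 1e-12 in
tests over 1,000 random parameter sets).

Key interpretation choices, fixed here as package behaviour:

- **Disposition weights are renormalized per decision context.** The
  source weights do not form a simplex (e.g. 0.68 + 0.20 + 0.25 + 0.26 +
  0.06 = 1.45); dividing by the context sum preserves their relative
  magnitudes while restoring total probability. A flag
  (`options.renormalize_dispositions`) disables this for sensitivity work.
- **"Suicide death 0.006" is conditional on an attempt**
  (`p_suicide_death_given_attempt`), since the tree resolves attempts
  exclusively into death or survival.
- **Carrier status.** Variant-class patients are carriers; normal
  metabolizers are non-carriers (`options.carrier_fraction` generalizes
  this). Carrier and non-carrier clinical rows are identical except one
  printed asymmetry (SoC CYP2C19 rapid metabolizers: side-effect
  probability 0.90 carrier vs 0.49 non-carrier), preserved as given.
- **Normal metabolizers** have no published clinical rows; the packaged
  default assigns response 0.37, side effects 0.30 (CYP2D6) / 0.49
  (CYP2C19) in both arms, and the strategy-specific relapse probability
  (0.099 PGx / 0.233–0.230 SoC). Rationale: the source applies the PGx
  relapse reduction even to classes whose dose is unchanged (ultra-rapid
  metabolizers), so the benefit is treated as guided drug selection, which
  also reaches tested normals. These are config rows, not code.
- **Costs per leaf** = first-line acquisition (half-dose entries for PM/IM
  under PGx) + lab/screening 560 + consultation 1,000 + genotyping 540
  (PGx only) + side-effect management (the sum of the priced side-effect
  items, 841) + relapse event 954 where applicable + disposition-specific
  components: switch adds a full alternative course (same cost row as
  first line, or the duloxetine override); titrate adds the
  increased-dose entry; discontinue adds the printed discontinuation entry
  plus an alternative course; an attempt adds 390, then 15 on death or
  1,300 plus an alternative course on survival. The printed
  discontinuation entries are used verbatim even where they are not half
  the first-line cost. Whether side-effect and relapse costs stack on
  relapse-with-side-effect leaves is unstated in the source; both are
  charged by default (`options.charge_relapse_and_se_costs`).
- **Success endpoints** are defined on the initial regimen: response
  without relapse, excluding or including side effects. Switched,
  discontinued-then-switched and post-attempt courses are "assumed
  successful" in the source; they contribute cost but, by default, not
  success (`options.count_switch_success` flips this).

### Markov model

Five states — response (without relapse), relapse, no response, suicide
death, non-suicide death — with everyone starting in response. Rewards
accrue on start-of-cycle occupancy; transitions then apply. One-off event
costs (relapse 1,908; suicide attempt 779; suicide death 29; non-suicide
death 2,040; post-attempt survival 2,600) are charged on incident
transitions; recurring costs (acquisition 648/595, follow-up 500, lab 560)
are charged per cycle alive — the charging cadence is configurable because
the source does not state it. The discount factor is continuous in cycle
time, `1.03^(−t)`; the optional half-cycle correction weights the first
and last cycles by one half.

The published transition block is internally inconsistent (duplicate
relapse rows; suicide-death and background-death entries of 0.117–0.118
per cycle, implausibly equal in magnitude to the response transition), so
two parameterizations ship:

- **`as_printed`** applies the block verbatim under the reading implied by
  its own row labels: the duplicate relapse rows sum; suicide death
  applies from the relapse and no-response states (its label says
  "without response"); non-suicide death applies from every living state;
  the "response" row is a return-to-response flow from both failure
  states; each living row closes with the remainder on self-transition.
  Rows whose printed entries exceed 1 are scaled down with a logged
  warning.
- **`reconciled`** (default) keeps the printed response/relapse/no-response
  dynamics but replaces the two death columns: background mortality is
  `1 − (1 − q(age))^0.25` from a fitted annual curve (below), age-varying
  unless age trends are disabled, and per-cycle suicide death is the
  context-renormalized attempt share times the fatality given an attempt
  (≈ 0.048 × 0.006 from relapse in the PGx arm). Attempt and
  post-attempt-survival costs follow the same per-cycle attempt stream.

Age-banded response utilities use the cohort's current age with half-open
bands [40, 50), …, [80, ∞). Utility of the death states is zero.

### Mortality curve

Annual all-cause mortality by single year of age is a least-squares
polynomial (default degree 2) through (band midpoint, annual rate) points,
clamped to [0, 1] on evaluation. No national life table is bundled; the
packaged schedule is a synthetic Gompertz stand-in (0.002/yr at age 48
doubling every 8 years, 5-year bands 45–84), clearly labelled as such in
the config and run manifests. Applied work must substitute a real
schedule; every lifetime-scale result below depends on it.

## Economics

ICER classification: dominant (cheaper, more effective) and dominated
strategies report no ratio; otherwise the ratio is compared with the
willingness-to-pay threshold (QAR 546,000 = USD 150,000 × 3.64 per QALY or
life-year). Net monetary benefit is `λ·ΔE − ΔC`. Cross-country cost
adaptation composes inflation, a per-capita health-expenditure correction,
a health price-level correction and the exchange rate, in that order; the
composition is recorded in a provenance record so alternative orderings
are a configuration change. Whether the source inflated before or after
currency conversion is unknown; the composition here is declared rather
than inferred.

## Uncertainty analysis

- **Distribution fitting.** Beta for probabilities and utilities, gamma
  for costs, method of moments with SD = (upper − lower)/3.92. Published
  intervals live in unavailable supplementary material, so the default
  plan assumes ±20% of the mean for probabilities (upper bound clamped to
  halfway between the mean and 1) and ±50% for costs, declared in
  `default_distribution_specs` and overridable per parameter. Gamma fits
  carry a minimum coefficient of variation (0.01) against degenerate
  intervals. Prevalences, the WTP threshold and the discount rate stay
  fixed in the PSA; the discount rate and genotyping fee are explored
  univariately at ±25% (triangular where sampled).
- **Sampling streams.** The master seed spawns one counter-based
  substream per parameter (`SeedSequence(seed, spawn_key=(j,))` over the
  sorted parameter ids), so runs are bit-reproducible and enlarging the
  draw count leaves earlier draws unchanged.
- **Evaluation.** The PSA evaluates both models with vectorized
  re-implementations over all draws at once; unit tests assert exact
  (1e-10) agreement with the reference single-draw code paths under both
  Markov variants. 50,000 draws complete in well under a minute on one
  CPU.
- **CEAC** is the fraction of draws with positive NMB per threshold;
  **tornado** ranking is ordinary least squares of the z-scored output on
  the z-scored sampled inputs jointly, constant columns excluded with a
  warning. Stepwise or mapped-value alternatives used by commercial tools
  are deliberately not imitated.

## Synthetic data

`synthetic.random_parameter_set` draws structurally valid parameter sets
(Dirichlet-split prevalence simplexes, uniform probabilities, gamma
costs, age-monotone utilities) and `synthetic_mortality_table` the
Gompertz schedule; both pass the single shared validator. They emulate
the *structure* of real inputs, not their joint distribution: parameters
are sampled independently, so correlation between e.g. response and
relapse in real data is absent. Property tests passing on synthetic sets
therefore establish bookkeeping correctness (probability conservation,
validator completeness, engine stability), not clinical realism.

## Numerical choices

- Probability bookkeeping is exact to 1e-12 (tree leaf sums, Markov row
  sums, occupancy conservation).
- Sampled probabilities are clamped to [0, 1]; over-full transition rows
  renormalize with a logged warning; mortality evaluation clamps to
  [0, 1].
- Validation collects *all* violations before raising, and missing config
  fields raise schema errors naming the field.
- Degenerate inputs: zero-valued parameters are held fixed in the PSA;
  zero context sums for dispositions raise; horizons shorter than one
  cycle run zero cycles.

## Known limitations

- Three published headline values are not reproducible from the published
  input tables, and the corresponding acceptance-suite tests fail by
  design rather than being weakened: (i) the short-term total costs
  (tens of thousands of QAR per arm) are an order of magnitude above any
  expected cost computable from the printed 6-week components — the
  packaged model prices the PGx arm ~QAR 437 dearer per patient, the
  panel fee minus partial offsets; (ii) the PGx lifetime cost per person
  depends on the mortality stand-in and lands ~26% above the published
  figure; (iii) the published QALY gain (0.06/person, less than half the
  life-year gain times any state utility) is unattainable in any
  five-state reading in which the longer-lived arm also occupies the
  better states. The per-person incremental life-years (0.128 under the
  default parameterization) do match the published 0.13.
- Long-term published totals mix at least two unreported cohort scales;
  the package reports per-person values and exposes a cohort multiplier
  (`LongTermResult.scaled`) instead of guessing.
- No post-relapse refractory-depression sub-model, no recurrence dynamics
  beyond the five states, no treatment sequencing beyond one switch, no
  indirect costs.
- The duloxetine-alternative scenario needs a course cost the source does
  not print; the packaged value is a placeholder and the scenario's
  absolute result is not meaningful until a real price is supplied.
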