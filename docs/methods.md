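# Methods

## The measurement model

Care complexity is modelled as the categorical product of two ordinal
instruments observed on different clocks:

* **Clinical instability** is the banded National Early Warning Score.
  Each of six physiological parameters maps through a band table to a
  sub-score in {0,1,2,3} (AVPU contributes 0 for Alert and 3 otherwise),
  and supplemental oxygen adds a fixed 2, so the total lies in 0–20.
  Bands: stable 0–4, unstable 5–6, critical ≥7. NEWS is observed per
  vital-sign measurement; the per-day analysis uses the **daily maximum**
  total, the most pessimistic reading of the day.
* **Care dependence** is the modified Index of Caring Dependence: eight
  care dimensions rated 1–4, summed to 8–32. It is assessed at admission
  and re-assessed at each care-setting transfer, so it is piecewise
  constant over the stay; each day carries the most recent assessment at
  or before it.
* The **Index of Caring Complexity** is a total, monotone 3×3 lookup from
  (band, level) to Low/Medium/High. In the shipped default, a critical
  band or a high dependence level is sufficient for High, and Low
  requires both inputs at their minimum. The matrix is config-loadable;
  monotonicity is enforced at load time because it is the substance of
  the model ("higher is more complex"), not a convention.

### Numerical conventions

* Band intervals are **closed on printed endpoints**. Values are compared
  after rounding temperature to 0.1 °C and the other parameters to
  integers, so 38.04 °C scores as 38.0 and there are no coverage gaps.
  Loading a band table verifies that each parameter's intervals are
  disjoint and jointly cover its sanity range (defaults: RR 0–80,
  SpO₂ 50–100, T 25–45, SBP 30–300, HR 0–300).
* A NEWS total of 0 is attainable and classifies as stable; the stable
  band is therefore 0–4 even though some printed headers start it at 1.
* **Two mICD cutpoint schemes** appear in the source material and are
  irreconcilable: the prose defines low 8–14 / average 15–23 / high
  24–32, while one printed table uses 8–16 / 17–25 / ≥26. The default is
  the prose scheme because the ICC matrix's columns are defined on those
  ranges; the alternative is selectable (`scheme="table8_bands"`) for
  reproducing that table as printed.
* Percentages in reports are rounded **half-up to one decimal**, matching
  the print format of the published tables; chi-square is the Pearson
  statistic without continuity correction, with a logged warning when any
  expected cell count falls below 5.

## Per-day and per-patient analyses

A hospitalization contributes one day row per calendar day from admission
(inclusive) to discharge (exclusive); a same-day admission/discharge still
contributes one row, which makes patient-days additive (the conservation
property the tests assert). Missing vitals on a day either raise
(`strict`) or carry the previous day's total forward with the first day
required present (`lenient`, the default for retrospective records, where
gaps are common).

Cross-tabulations and the consistency analysis treat patient-days as
independent units. Days within one stay are correlated, so the chi-square
p-values attached to per-day tables describe the allocation pattern, not
patient-level inference; this is a documented caveat of the design being
reproduced, not something the package "fixes".

The per-patient analysis classifies each admission by its admission-day
ICC (first admission-day vitals + the admission mICD) and tabulates
mortality, transfer to higher care, length of stay and the pass-through
DRG value against it. Records lacking an admission assessment are
reported and excluded from that table only.

Allocation consistency compares each day's ICC with the class its setting
is expected to host — sub-intensive→High, high→High, medium→Medium,
low→Low by default, overridable because the mapping is itself a policy
choice.

## The synthetic-cohort generator

The generator emulates the structure of the studied cohort, not its
records. The default configuration fixes: 349/39/62 patients across
internal medicine, neurology and pneumology; exactly 2,884 patient-days;
and per-ward gender, age-class, stay-length-class, setting and outcome
mixes plus per-setting daily NEWS-band and mICD-level mixes, all
proportional to the published contingency-table counts (only internal
medicine allocates patients to low care, neurology records no deaths,
and so on). Admissions are staggered uniformly over a 31-day window.

Choices the printed material does not constrain, fixed once as realistic
defaults: age classes realized uniformly within their bounds (open
classes capped at 30–59 and 91–99 years), the open stay class capped at
16–30 days, a 10 % chance of one within-stay setting transfer, and a
log-normal DRG value (μ=8.1, σ=0.5 on the log scale, ≈ €3,300 median).
The joint distribution of ward × setting × band beyond the printed
marginals is an explicit modelling choice — mixes are sampled
independently conditional on the day's setting.

**Latent-first sampling.** Each day first draws its latent instability
band (per-setting mix) and each setting interval its latent dependence
level; concrete vitals and rubric levels are then realized *inside* the
parameter regions that score back into that class. Totals are drawn
uniformly within the class range (critical totals capped at 12, the
clinically plausible bulk of the ≥7 band), distributed over components
under their attainable sub-score sets, and parameter values drawn
uniformly on the matching interval (temperature on a 0.1 °C grid so
rounding cannot cross an endpoint). This guarantees the round-trip
property — re-scoring generated data reproduces the latent classes
exactly — and gives exact control of the class mixes.

**Exact day totals.** Sampled lengths of stay are repaired to the
configured total by ±1-day perturbations of uniformly chosen patients
(never below one day), so the only printed day total is reproduced
exactly while class structure is approximately preserved.

**Two severity modes.** With `mismatch_rate=None` (the default
configuration) severity mixes are conditioned on the assigned setting as
observed, so allocation inconsistency appears at realistic rates. With
`mismatch_rate=m` each patient's complexity is drawn *consistent* with
the assigned setting and a Binomial(m) fraction of patient-days is then
re-assigned to a setting inconsistent with its ICC, uniformly among the
inconsistent ones — a known ground truth (overall consistency 1−m) used
to validate the analysis chain. The two modes are mutually exclusive by
construction: the same days cannot both match observed mixes and a
prescribed mismatch rate.

**Reproducibility.** One root seed is split via `numpy.random.SeedSequence`
into four streams in a fixed order (patients → days → vitals →
dimensions), so extending one sampling stage never shifts another's
draws; same config + seed reproduces the cohort bit for bit.

### What passing tests do and do not show

The generator matches marginal structure, not clinical dynamics: vitals
are independent across days (no autocorrelation or trajectories), the
within-stay transfer process is a single random split, admission volume
has no day-of-week or epidemic structure, and dependence levels are
independent of age and outcome. Tests passing on synthetic cohorts
demonstrate that the pipeline's bookkeeping, classifications and
statistics are correct — not that the instruments are valid on real
patients.

## Problem sizes and tolerances

The test suite exercises the full 450-patient / 2,884-day configuration
where exactness matters (cohort sizes, day totals, mismatch recovery) and
scaled-down cohorts (30–40 patients, 200–300 days) for structural
round-trip properties. Stochastic recovery checks use 3 Monte-Carlo (or
binomial) standard errors as their acceptance band; worked-example table
cells are asserted exactly at printed precision. Published cells that are
internally inconsistent (one column of the instability table sums to 426
against a printed 422; one row's percentages disagree with its counts)
are shipped in fixtures as printed but not asserted.

## Known limitations

* The scoring form is the 2012 NEWS; the 2017 NEWS2 hypercapnic SpO₂
  scale is out of scope.
* Free-text rubric descriptors are not parsed; the software accepts the
  numeric 1–4 level, treating text-to-level mapping as clinical judgement.
* No causal or adjusted modelling of outcomes is attempted; the
  per-patient table is descriptive.
* Economic (DRG) values are pass-through numbers with no grouper logic.
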