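# Methods

## Problem and model

The quantity of interest is the worldwide number of current e-cigarette
users: the sum over countries of prevalence × adult (15+) population.
Prevalence is observed only where a qualifying survey exists (a recent
general-population survey reporting current use, defined as use at least
once in the last 30 days); elsewhere it must be imputed.

The imputation model is *average similarity*: countries sharing a subgroup
of three categorical factors — WHO region (6 levels), World Bank income
classification (4 levels), and legal status of e-cigarette sale (3 levels)
— are assumed to have similar prevalence, so an unsurveyed country receives
the unweighted mean of the observed prevalences in its subgroup. Because
many of the 6×4×3 = 72 three-factor subgroups contain no surveyed country,
subgroups are tried through an ordered fallback cascade, from most to least
specific:

1. region × income × legal
2. income × legal
3. income × region
4. region × legal
5. income
6. global mean over all surveyed countries

Each step fills only the blanks left by the previous step, so the procedure
is a deterministic function of the input table, and step 6 guarantees full
coverage whenever at least one survey exists (imputation with zero surveys
is a hard error). Every value carries provenance: level 0 is an observed
survey value (passed through bit-exact, never overwritten), levels 1–6 name
the cascade step and group key that produced the value.

"Unknown" is an explicit level of every factor, not a missing field. A
country with an unknown factor cannot form a key at any level whose
signature includes that factor and falls through to later levels; in
reports it lands in an "Unknown" row of that factor's breakdown while still
contributing fully to the world total.

## Goodness of fit

Each group mean carries a simplified confidence interval,
mean ± z·sd/√n, with sd the sample (n−1) standard deviation of the
contributing countries' prevalences, truncated below at zero. With a single
contributor the sd is undefined and the interval is reported as unavailable
rather than fabricated as zero-width; a zero-sd group yields the degenerate
interval (mean, mean). The multiplier z defaults to 1.96 and is
configurable, since the interval is a heuristic fit diagnostic, not an
exact sampling interval: contributing countries are not a random sample of
their subgroup.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| cascade order | the six signatures above | fallback sequence; must end with the global signature |
| `z` | 1.96 | interval half-width multiplier (dimensionless) |
| `min_group_n` | 1 | minimum surveys for a subgroup mean to be used (the terminal global mean is exempt, so coverage is preserved). 1 by default: a single data point is deliberately allowed to represent a subgroup, which is exactly how sparse regions behave in practice |
| `population_weighted` | off | weight subgroup means by adult population instead of one-value-per-country |
| survey-year window | 2012–2020 | inclusion criterion for survey observations |
| projection `mode` | `index` | `index`: total × revenue ratio; `correlation_damped`: total × (1 + ρ·(ratio − 1)) |
| `rho` | 0.933 | revenue–prevalence correlation used only by the damped mode; a supplied constant, not re-estimated, because the underlying national revenue series is proprietary. `pearson_correlation` lets users with their own series recompute it |
| base year | 2018 | calibration year of the market index and reference year of populations |

The default projection mode is `index` because the raw revenue ratio is the
arithmetic that turns the 2018 world estimate into the reported ≈68 million
for 2020; the damped mode is the most plausible reading of "adjusting the
proportions by the correlation coefficient" and gives ≈67.3 million.
Reporting always shows both modes side by side rather than silently
choosing.

## Units and numerical choices

- Prevalence is a fraction in [0, 1] in memory; all file and report I/O is
  in percent. Report percentages are rounded half-up to 2 decimals, and
  user counts half-up to whole persons, only at render time.
- Aggregation is done in exact rational arithmetic (`fractions.Fraction` of
  the float prevalences), so group totals conserve the world total exactly
  across every partition — equality, not closeness, is tested.
- A subgroup whose contributors all share one value means exactly that
  value (no floating-point drift from summation), which makes zero-variance
  recovery exact.
- Tables are stored sorted by ISO3 code, so row order in input files is
  irrelevant; ties never arise because the cascade is a strict first-match
  scan.
- CSV round-trips preserve prevalence to ~1e-12 relative (percent
  serialization at full repr precision); all other fields round-trip
  exactly.

## Synthetic worlds

The generator emulates the structure the method assumes, with a hidden
truth for scoring:

- **Factors** drawn independently per country from marginals matching the
  observed composition of the world's ~200 countries, including small
  "unknown" masses (1% region, 0.5% income) to exercise the Unknown rows.
- **True prevalence** is inverse-logit(baseline + region effect + income
  effect + legal effect + noise), with baseline logit(0.012), effects on
  the log-odds scale sized so subgroup prevalences span roughly 0.2–7%
  (richer, permissive countries vape more), and country-level noise sd 0.5.
  The noise sd is the dial that controls how badly the similarity
  assumption fails; at sd = 0 prevalence is an exact function of the
  three-factor key.
- **Adult populations** are log-normal per income group (location ≈ e^16–e^17
  ≈ 10⁷ persons, scale 1.3–1.8), spanning ~10⁵–10⁹.
- **Survey masking** depends on income group only, with probabilities
  {high 0.87, upper-middle 0.77, lower-middle 0.09, low 0.055} — the real
  coverage bias; a hook allows population-size-dependent masking. Observed
  values equal truth exactly unless a survey noise sd is set.
- One PCG64 generator (`numpy.random.default_rng`) seeded explicitly;
  replicate *r* of an experiment uses seed + *r*; everything is
  deterministic given the seed.

What the generator does *not* emulate: spatial correlation beyond the
factor structure, correlation between factors (region and income are drawn
independently), within-country survey sampling error by default,
multi-survey countries, and population growth over time. Passing recovery
tests therefore show that the pipeline is correct *given* the similarity
structure, not that the similarity assumption holds for real countries.

The recovery experiment (default 201 countries; test suites use 5–100
replicates, sized so the whole suite runs in seconds) generates, imputes,
aggregates and compares the estimated world total to the true one. Under
the default income-biased masking the estimated total is biased upward by a
few percent — surveyed countries are richer and vape more, so their means
propagate into poorer unsurveyed strata — quantifying the known tendency of
this method to overestimate; with uniform full coverage the error is
exactly zero.

## Known limitations

- One prevalence per country: multiple surveys must be reconciled upstream.
- Subgroup means ignore within-group population structure unless
  `population_weighted` is switched on; the default mirrors one-value-per-
  country averaging, which is what the method as published does.
- The goodness-of-fit interval is unavailable for single-survey groups —
  precisely the groups where the estimate is weakest.
- The market projection assumes user numbers move proportionally with
  (possibly damped) revenue, ignoring price and consumption-intensity
  changes; both modes are reported to surface that ambiguity.
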