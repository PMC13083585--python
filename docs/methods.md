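# Methods

Statistical definitions, generator design, numerical conventions and
known limitations of the `dystosignal` pipeline.

## 1. Data model and ingestion

A quarterly bundle consists of dollar-delimited ASCII tables: DEMO (one
row per report version), DRUG (one row per drug mention, with a role
code: PS primary suspect, SS secondary suspect, C concomitant, I
interacting), REAC (one row per MedDRA preferred term), THER (therapy
start/end dates per drug sequence), OUTC (outcome codes, merged onto
the demographic record) and an optional deleted-case list.

Dates arrive as `YYYYMMDD`, `YYYYMM`, `YYYY` or blank/garbage. The
parser is total: every input maps to a `DateValue` carrying the raw
string, a precision tag (`day`, `month`, `year`, `missing`) and an
ordinal defined only at day precision. **No date is ever imputed**;
downstream stages either require day precision (time-to-onset) or order
conservatively (deduplication, where any non-day date sorts below every
day-precision date). Rows missing PRIMARYID or CASEID are a hard error:
silently dropping them would corrupt case-level counting.

## 2. Deduplication

FAERS reports are versioned: one case (CASEID) accumulates report
versions (PRIMARYID) over time. For each case the pipeline keeps the
version with the largest FDA receipt date (FDA_DT), breaking ties by
the largest PRIMARYID compared numerically (leading zeros stripped).
Deleted-case lists from all quarters are applied after version
selection, cumulatively. The invariant `parsed = retained +
removed_as_duplicate + removed_by_deletion` is recorded in the run
manifest and asserted in tests.

## 3. Case definition and contingency tables

A retained report is a *case* when any of its reaction preferred terms
matches the target query (case-insensitive, whitespace-normalized).
Drug exposure is taken from DRUG rows with the configured roles
(default: primary suspect only for single-drug signals; PS+SS for
interaction screening), mapped through a verbatim→canonical normalizer.
For each canonical drug the 2×2 table over retained reports is

|            | event (case) | non-event |
|------------|--------------|-----------|
| drug       | a            | b         |
| other drugs| c            | d         |

with `a+b+c+d = N` (all retained reports).

## 4. Disproportionality statistics

With `N = a+b+c+d`:

- **ROR** `= ad/(bc)`, Woolf interval
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
- **PRR** `= [a/(a+b)] / [c/(c+d)]`, with the uncorrected Pearson
  `χ² = N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]`.
- **BCPNN** information component
  `IC = log2[(a+0.5)/(E+0.5)]`, `E = (a+b)(a+c)/N`, with the
  closed-form lower bound
  `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`. This is the standard
  published approximation, not a Monte-Carlo posterior quantile.
- **MGPS** `EBGM = aN/[(a+c)(a+b)]`, with
  `EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d))` (a 90% lower
  bound, z = 1.64). The sum of reciprocal cells enters under a square
  root — the usual normal approximation on the log scale.

Flags, each additionally requiring `a ≥ 3`:
ROR lower bound > 1; PRR ≥ 2 **and** χ² ≥ 4; IC025 > 0; EBGM05 > 2.
A drug is a **positive signal** only when all four flags fire
(conjunction rule). When any cell is zero, a Haldane–Anscombe +0.5 is
added to every cell for ROR/PRR/MGPS (BCPNN's own +0.5 shrinkage
already handles zeros); the correction is recorded on the result.

Useful identities asserted in tests: `ROR/PRR = (1+a/b)/(1+c/d)` sits
on the same side of 1 as ROR, so `sign(ROR−PRR) = sign(ROR−1)`; and
`2^IC ≤ EBGM` whenever `EBGM ≥ 1`.

## 5. Time to onset

For each (case report, exposed drug), onset is `event_dt −
start_dt` in days, where the start is the *earliest day-precision*
therapy start among that drug's therapy rows on the report. Records are
excluded — never imputed — with a tallied reason: `missing_start`,
`partial_precision` (month- or year-only date), `missing_event`,
`negative` (event before start), `inconsistent` (therapy end before
start). Same-day onset (0 days) is valid.

Onset distributions per drug are compared with the Kaplan–Meier
product-limit estimator (case-only data has no censoring, so
`1 − S(t)` equals the empirical CDF exactly — asserted in tests), the
k-sample log-rank test (χ², k−1 degrees of freedom), and the
Kruskal–Wallis rank test as a descriptive supplement. These are backed
by `lifelines` and `scipy.stats`; the module's own tests check them
against hand-computed product limits and closed-form oracles.

## 6. Drug-drug interaction screening (Ω shrinkage)

For an unordered drug pair, retained reports split into four exposure
strata: both drugs (count `n11+`, events `n111`), A only, B only,
neither, with event proportions `f10`, `f01`, `f00`. The observed
`n111` is compared to its expectation `E111 = g111·n11+` under a
no-interaction baseline:

```
Ω     = log2[(n111 + 0.5) / (E111 + 0.5)]
Ω025  = Ω − 1.96 / (ln 2 · √n111)
```

A pair is flagged when Ω025 > 0. The half-width `z/(ln 2·√n111)` was
verified to reproduce all four published lower bounds (0.06, 1.65,
0.09, 0.67) from their printed (n111, Ω) pairs to two decimals.

The baseline `g111` is pluggable because the surveillance literature
does not fix one convention:

- `odds_additive` (default): `odds(g111) = odds(f10) + odds(f01) −
  odds(f00)`, floored at the larger single-drug odds;
- `multiplicative`: `1 − g111 = (1−f10)(1−f01)/(1−f00)`;
- `max_single`: `g111 = max(f10, f01)` (no synergy);
- `odds_multiplicative`: `odds(g111) = odds(f10)·odds(f01)/odds(f00)`
  — matches the synthetic generator's effect composition, so it is the
  correctly-specified baseline for generator-driven calibration tests.

Degenerate strata (empty denominator, or proportion 1 giving infinite
odds) fall back along that list, and the model actually used is
recorded per pair. Published acceptance targets depend only on
(n111, Ω), not on the E111 model.

## 7. Synthetic generator

Each simulated case draws: 1–5 drugs from the catalog (independent
presence by marginal probability, forced to at least one, capped at 5),
a reporter occupation, demographics, and a target-event indicator with

```
log-odds(event) = logit(p0) + Σ_present log(multiplier_d)
                + Σ_present-pairs log(excess_ab)
```

capped at probability 0.99 (a warning is emitted when the cap binds on
a non-trivial fraction of cases). Effects are specified on the odds
scale so injected multipliers are directly comparable to the ROR the
pipeline estimates — parameter recovery is a clean acceptance test.
Non-target reaction terms are drawn independently by their catalog
probabilities.

Onset: the primary suspect's drawn time-to-onset (exponential, Weibull
or lognormal, parameterized by median; floored to whole days) anchors
`event_dt = start_dt + tto`; other suspect drugs on the same report are
back-dated `start = event − tto_d` so each drug's configured onset
distribution is preserved marginally.

Realism knobs, all ledgered per case: duplicate report versions with
strictly increasing FDA_DT; deletion lists; per-field missing-date
blanking (default 0.55 per field, giving ≈20% of reports a complete
start/event date pair); reporter-occupation mix; and *lawyer bias* —
extra lawyer-submitted event reports for a chosen drug, Poisson-volume
on top of its base event reporting. That mechanism inflates the event
background (`c`) for every other drug, which is what makes
lawyer-exclusion sensitivity analysis enlarge the positive-signal set.

`truth_check` verifies a bundle set against its ledger (primaryid
consistency, version ordering, deletion and event flags).

## 8. Sensitivity analysis

`sensitivity_exclude` drops all retained reports from one reporter
occupation (lawyers by default) *after* deduplication and recomputes
every signal. The output records baseline/filtered positive sets and
the gained/lost drugs. Under the litigation-bias generator condition,
exclusion enlarges the positive set in ≥90% of seeded replicates
(acceptance criterion 7).

## 9. Numerical conventions

- Percentages are computed in decimal arithmetic and rounded half-up to
  2 decimals (`Decimal`, not binary-float banker's rounding), so
  printed shares like 54.84 = 15146/27618 reproduce exactly.
- Outcome percentages are per-code against the case total; a report can
  carry several outcome codes, so they intentionally do not sum to 100.
- Age bands convert units (YR/DEC/MON/WK/DY/HR) to years; unknown units
  route to the `unknown` band with a warning.
- The pipeline is deterministic given a config: reruns are byte-
  identical (asserted in tests).

## 10. Known limitations and open decisions

- IC025 uses the closed-form approximation; exact posterior quantiles
  from a full Bayesian treatment would differ in the third decimal and
  published per-drug IC025 values are not reproducible under any
  standard closed form, so they are not targets.
- EBGM05 here is the z = 1.64 log-normal approximation, not the true
  posterior 5th percentile of a fitted gamma-mixture prior.
- The Ω interval is symmetric with half-width depending only on n111 —
  a shrinkage-measure convention, not a likelihood-based interval.
- The generator composes effects multiplicatively on the odds scale;
  real reporting dependence between drugs on a report (co-prescription
  structure) is not modeled beyond forced multi-drug draws.
- Database-scale published counts (tens of thousands of dystonia
  reports; a positive-signal list of ~100 drugs) require the full
  multi-year data download and are out of scope; acceptance rests on
  self-contained printed values and property-based suites.
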