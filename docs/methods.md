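# Methods

## Trial structure and data model

A trial consists of seed lots (species × provenance), each sown under two
treatments — bare seed and pellet — with 50 replicates of 3 grouped seeds
per arm. Emergence is scored on a weekly census (days 7…126, 18 weeks):
a replicate's emergence day is the first census at which any of its seeds
has produced a seedling, so event times are interval-censored and
right-snapped to the census grid; replicates with no emergence by trial end
are recorded as never emerged. Survival is a single post-plateau binary
recorded only for emerged replicates. The loader enforces these invariants
(survival present iff emergence present; emergence days on the schedule
when one is supplied) and reports every offending row by index.

Day coordinates are integer days after sowing. The census grid is not
hard-coded: the metrics accept arbitrary positive emergence days, because
published per-lot spreads include values that are not multiples of seven
(the underlying deposit evidently used finer timing than the printed
weekly grid).

## Emergence metrics

For one arm with `n_sown` replicates of which `n` emerged on days `t_r`:

* total emergence = `100 · n / n_sown` (%);
* survival = `100 · n_alive / n` (% of **emerged**, not sown — a lot can
  have 2% emergence and 100% survival);
* time to emergence: `t_first = min t_r`, `MTE = mean t_r`,
  `t_last = max t_r`;
* time spread `TSE = t_last − t_first` (days);
* emergence rate index `ERI = Σ_i n_i / t_i` over distinct census days
  (Maguire's index on a count basis, emergents·day⁻¹). A percent basis
  (`Σ_i 100·n_i/(n_sown·t_i)`), matching a %/day reading of the index, is
  available via `eri_basis="percent"`; the count basis is the default
  because it reproduces the published zero-spread rows exactly
  (e.g. 50 emergents all on day 14 → 50/14 = 3.57).

All speed metrics and survival are undefined (None, exported as empty
cells) for an arm with no emergents. Useful identities: with all emergents
on one day `t`, MTE = `t`, TSE = 0 and ERI = `n/t`; in general
`n/t_last ≤ ERI ≤ n/t_first`, and ERI is monotone non-decreasing as any
emergence day moves earlier. Display rounding is half-up (2 decimals for
ERI, integers for percentages and days); all internal comparisons use
unrounded values except where a working precision is stated below.

## Percent → count inversion

The packaged published table prints integer-rounded percentages. For
`n < 100`, rounding a true percentage `100·c/n` to an integer loses less
than half a count: `|round(pct)·n/100 − c| ≤ n/200 < 0.5`. Hence
`counts_from_percent(pct, n) = ⌊pct·n/100 + 0.5⌋` recovers the exact
count — verified exhaustively for all `0 ≤ c ≤ n ≤ 99` in the tests. This
holds for emergence counts (denominator 50, so printed percentages are
even integers; an odd value is rejected as a transcription error) and,
applied with the emerged count as denominator, for survivor counts.

## Treatment comparisons

**Emergence and survival** use Pearson's χ² of independence on the 2×2
table (outcome, no outcome) × (bare, pellet), one species at a time, with
the closed form `X² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` and a 1-df
χ² reference distribution. The **Yates continuity correction**
(`|ad−bc| → max(0, |ad−bc| − N/2)`) is applied by default. This default
mirrors R's `chisq.test` on 2×2 tables — the convention under which the
published per-species classification counts are reproduced exactly — and
can be disabled (`correction=False`); `correction_sensitivity()` reports
every species whose direction depends on the flag, each of which
necessarily has p-values straddling α. A zero-margin table (e.g. all
replicates surviving in both arms) carries no information: the test is
reported as no-difference with p = 1 and a warning rather than NaN.
Directions are assigned only at p < α; α = 0.05 throughout, with **no
multiple-testing adjustment** across species — deliberate, since the
classification rules consume per-species decisions, but it means
individual labels near the threshold are fragile.

Species with zero emergence in both arms are dropped entirely; species
with zero emergence in one arm keep their emergence test (0/50 against
the other arm) but have no defined survival contrast and are excluded from
the survival analysis and hence from amenability ranking.

**Mean time to emergence** is modelled on the emerged replicates'
emergence days with a linear mixed model: species, treatment and their
interaction as fixed effects and a random intercept per lot. The global
treatment p-value comes from the additive model's Wald test; per-species
pellet−bare contrasts are Wald tests on the interaction model's linear
combinations (unadjusted, ML fit). Replicate-level random effects are not
identifiable with one observation per replicate, which is why the random
intercept sits at lot level. Species with fewer than 4 emerged replicates
in either arm are dropped from this model. If the fit degenerates
(singular covariance, non-finite standard errors), the model falls back to
per-species Welch t-tests and records the fallback in the result. Gaussian
errors on a weekly-censored day scale are an approximation; contrasts are
z-based and anti-conservative for very small emergent counts, one reason
the classification rules treat this metric as only one vote of three.

**ERI and TSE** are lot-level quantities (one value per arm), so the
global treatment test is a mixed model `value ~ treatment` with a species
random intercept. Within species they are compared **by value**, not by
test, at a working precision of 2 decimals — the printed precision of the
published table — with exact ties labelled equal.

## Classification rules

Amenability (defined when both emergence and survival comparisons exist):
*high* if both directions ∈ {pellet-higher, no-difference}; *low* if both
are pellet-lower; *medium* otherwise (exactly one worse). The rule is
monotone: improving either direction never lowers the label. Emergence
speed: per metric, faster = significantly shorter mean time, higher ERI,
or shorter TSE in pellets; the overall label is the majority over the
defined metrics, requiring at least two defined; when no label reaches two
(one each of faster/slower/equal) the species is called *equal* — the
least assertive resolution of a case the rules otherwise leave open. Every
label carries a `rule_trace` naming the clause that fired.

Two-provenance species are pooled before testing (the default): emergence
and survivor counts summed across provenances; lot-level speed metrics
combined as emergence-weighted means, which also resolves provenances that
disagree in direction. A `per_lot` mode keeps lots separate for data laid
out that way. Working from the packaged published table, only ERI and TSE
are available as speed metrics (replicate-level times are not printed), so
the overall speed label there rests on those two; the mean-time vote
requires replicate-level input.

## Reproduction scope of the packaged table

The packaged fixture supports exact reproduction of: trial-wide emerged
totals (1669 bare / 1616 pellet), the per-species emergence classification
(17 higher / 21 lower / 20 no-difference of 58 species) and the survival
classification (37 no-difference / 4 higher / 12 lower of 53), all under
the default corrected test. Three published counts are **not** exactly
recovered and the corresponding checks are expected to disagree by 1–3
species: the joint amenability tally (this pipeline: 31 high / 13 medium /
9 low vs 30/15/8) — the original amenability combination used mixed-model
pairwise contrasts fitted to replicate-level data, which can flip species
whose χ² p-value sits within a few hundredths of α (two borderline
survival tests, p ≈ 0.055 and p ≈ 0.017, are exactly the gap) — and the
ERI/TSE value tallies (25 and 24 here vs 24 and 21), which depend on
near-ties that 2-decimal printed values cannot resolve. The package
reports what the printed data imply rather than tuning to the published
tallies.

## Synthetic trials

The generator emulates the design: per seed, germination is Bernoulli
(`p_seed`), so replicate-level emergence probability is
`1 − (1 − p_seed)³`; germinated seeds draw emergence times from a
lognormal (default; `median_days`, `log_sd` — right-skewed and positive,
a standard choice absent information on the true shape; a
median-matched gamma is available); the replicate's day is the earliest
seed time snapped *up* to the next census day, censored past day 126;
survival is an independent Bernoulli for emerged replicates (a hook point
if time-dependent survival is ever needed). Defaults mirror the study:
50 replicates × 3 seeds, weekly censuses to day 126. Everything is driven
by one `numpy` Generator, so a fixed seed reproduces a dataset exactly.

`design_amenability_cohort` builds a 30/15/8 high/medium/low cohort (the
published label proportions) with arm effects large enough that each
constituent χ² is powered far beyond 0.99 at n = 50 (e.g. replicate-level
emergence 0.55 vs 0.95), so label recovery failures measure pipeline
defects rather than sampling noise; designed-null responses are placed so
that a type-I error cannot change the label except through a
significantly-worse flip (~2.5% per test). What the simulator does *not*
emulate: spatial tray effects, re-randomization, weather-coupled watering,
correlation between emergence time and survival, and overdispersion
between replicates beyond the binomial — so passing recovery tests
validate the statistical machinery, not robustness to those features of
real greenhouse data.

## Problem sizes in the test suite

Simulation-backed checks are sized to keep the default run fast while
leaving binomial error well inside the asserted bands: 20 seeds × 53
species for label recovery, 500 simulated null tables for the χ²
calibration check (±3·SE ≈ ±0.029 around α), 3 seeds × 16 species for the
mixed-model delay-detection check, and 300 simulated null one-way trait
models.

## Known limitations

* Per-species inference is unadjusted for multiplicity by design; treat
  individual borderline labels, not the aggregate tallies, with caution.
* The mixed models use ML Wald tests (no Satterthwaite/Kenward-Roger
  small-sample correction); with ≤ 4 emerged replicates per arm their
  per-species contrasts are approximate.
* The survival χ² can involve very small emerged denominators, where the
  asymptotic reference distribution is rough; an exact-test option is a
  natural extension but is not the convention the published counts follow.
* Trait models treat performance rank as categorical, not ordinal; height
  for shape variance defaults to `h = w` when plan-view imaging provides
  no depth, and species where this fallback fired are flagged.
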