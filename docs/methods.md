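# Methods

## Data model

Inputs are two daily tables from a constant-effort ringing station:
captures (date, species, sex, optional age, count — one row per bird or
per aggregated count) and effort (date, metres of mist-net, hours open;
one row per operated day). Non-operated days (weather closures) are
absent from the effort table and propagate as *missing*, never zero: a
zero would drag the moving average down near closures and bias both the
peak and the threshold crossings. Species are mapped to wintering groups
(North Africa / Sahel / Tropical) by a metadata table; a 30-species
assignment for a Tyrrhenian-island spring stopover station ships with
the package together with typical passage statistics used by the
simulator defaults.

### CPUE

Daily intensity is catch per unit of effort,
`CPUE_d = scale · n_d / (L_d · H_d)` with `scale = 100` (captures per
100 net-metre-hours). The effort denominator is the product of net
length and hours open; only the ratio structure matters downstream,
because the peak and the window threshold are defined *relative* to the
same series — every phenology metric is invariant to the scale constant
and to any fixed redefinition of the effort unit. Conservation holds by
construction: summing `CPUE_d · L_d H_d / scale` over operated days
returns the raw capture total.

## Phenology extraction

* **Smoothing**: centred 7-day moving average on calendar days. Missing
  days inside a window are dropped from the mean (not zero-filled,
  not interpolated — a closure day carries no information about passage
  intensity); at the season edges the window shrinks so the MA exists on
  the first and last season day, which the truncation rule requires.
  A trailing window was rejected: it would shift every date late by
  ~3 days.
* **Peak**: the day with the highest MA; ties resolve to the earliest
  day (deterministic, and unbiased for symmetric waves).
* **Window**: scanning outward from the peak, the start (end) is the
  *nearest* day whose MA falls strictly below 10% of the peak MA. The
  bound is the sub-threshold day itself. The nearest-crossing convention
  defines one contiguous main migration period around the peak and is
  robust to multimodal tails; taking the outermost crossing instead
  would let isolated late stragglers inflate the window. Undefined-MA
  days are skipped during the scan.
* **Truncation**: if the scan exhausts the season while the MA is still
  at or above the threshold, that bound is undefined and flagged — no
  date is fabricated. This is what protects trend estimates from
  censoring bias when a season opens mid-passage (typical for the
  earliest, short-distance migrants).
* **Exclusion**: species-years with fewer than 5 raw captures are
  excluded outright (a 7-day MA of 4 birds has no usable shape).

This construction is insensitive to the shape of the daily distribution
and avoids quantile-based dates (median, percentiles), which are not
estimable from a truncated sample.

## Trend estimation

Per species and metric, OLS of the annual value on calendar year; the
slope is the average yearly change (days/year, negative = advance), with
the usual t-test. At least 3 usable years are required; fewer yields a
flagged, undefined estimate rather than a silent drop. Degenerate exact
fits are closed out explicitly (zero residual variance ⇒ p = 1 for a
zero slope, p = 0 otherwise). Regressions are unweighted; annual sample
size is carried in the metrics table for diagnostics.

## Group comparison

Annual metric values pool across species within wintering groups in a
linear mixed model with group, year and group × year fixed effects and
a random intercept per species, fitted by REML (statsmodels `MixedLM`;
a cascade of optimizers guards against singular inner solves when a
variance component collapses to zero). Design choices:

* **Random intercept only.** Species differ widely in mean passage
  date; the intercept absorbs that. Random year-slopes are a possible
  extension, not the default.
* **Year centred at 2002** (first study year) for conditioning; slopes
  are unaffected, and the test suite checks invariance to the centring
  origin and to the reference group at 1e-8.
* **Marginal slopes** are linear contrasts `c'β` with variance `c'Σc`
  from the fixed-effects covariance — the year coefficient plus the
  group's interaction term.
* **Wald z p-values** for marginal slopes and pairwise contrasts. With
  ~18 years × ≥6 species per group the z approximation is good;
  finite-sample df corrections (Satterthwaite, Kenward–Roger) are out
  of scope and the model-level coefficient tests are reported as bare
  t-values.
* **No multiplicity adjustment** by default for the 1–3 pairwise
  contrasts; the alpha-sweep machinery makes the dependence on the
  chosen level explicit instead.
* **Start and window comparisons drop the North Africa group** by
  default: its species' passage typically begins before the station
  opens, so their start dates are mostly truncated/undefined and the
  group cannot contribute those metrics.

### Compact letter display

Pairwise contrasts are summarized by the insert-and-absorb algorithm:
groups share a letter iff their slopes do not differ at the chosen
alpha. Tested against exhaustive clique-cover enumeration for up to five
groups (contract + letter-minimality). Because a letter display answers
only at a fixed alpha, the sweep repeats it over an increasing alpha
grid and reports, per pair, the bracketing grid interval where the
separation flips — the honest way to report a non-significant contrast
as `a < p < b`.

### Sex-specific analysis

For species whose sexes are separable in the hand, the same machinery
runs per sex (group × year mixed models for males and for females) and
per group (sex × year interaction — a protandry-trend test), plus
per-species per-sex OLS trends. Between-group sex comparisons default to
Sahel vs Tropical: a group with a single dimorphic species would make
the species random effect singular, and the code refuses it by name.

## Simulator

Each species is a Gaussian passage wave: in year *y*,
`mean = μ0 + β (y − y0)`, `sd = σ0 + γ (y − y0)` (floored at 1 d).
Expected daily counts are `λ_d = V · f(d) · e_d / ē` — annual volume
times the wave density times the day's relative effort — and observed
counts are Poisson on operated days only. Effort has mean-one lognormal
day-to-day jitter (so expected totals are effort-free), ~1% of season
days are lost at random, and dimorphic species split into a male wave
shifted −δ/2 and a female wave +δ/2 (protandry δ, default 3 d, male
fraction 0.5). One `numpy` Generator seed drives everything; a fixed
seed yields byte-identical output files.

Defaults are the study design the analysis targets: 18 years
(2002–2019); the 30 packaged species with their groups, volumes, and
per-species peak trends; season Julian days 70–150; 227 m of net open
14 h/day. Baseline peaks are back-shifted by half the trend so the
simulated *mid-study* passage matches the tabulated median passage
date. σ0 is 8 d (≈ 34-day window at the 10% threshold, matching
reported 25–40-day windows) except North-Africa winterers at 12 d:
short-distance migrants have a more protracted early passage, which is
also what makes their start dates truncate at the season opening, as
observed.

What the simulator does *not* emulate — and therefore what passing
tests do not certify about real data: asymmetric or multimodal waves
(a skew/two-component mode is the obvious extension), day-to-day
weather-driven arrival pulses (counts are conditionally independent
Poisson), overdispersion, between-year correlation in effort or timing,
and any covariate structure (climate indices are out of scope). Because
the generator shifts the whole wave, simulated start/end trends mirror
the peak trend unless a spread trend γ is set; real data can decouple
them.

## Numerical notes

* MA via pandas `rolling(center=True, min_periods=1)`, which implements
  exactly the shrink-at-edges / skip-missing semantics.
* Peak ties → earliest day; all scans are integer-day and exact.
* OLS via `scipy.stats.linregress`; mixed models via statsmodels REML,
  verified in-suite against an independent profiled-deviance grid
  search.
* Problem sizes in the test suite: the smoothing oracle runs 1,000
  random series; trend-test calibration uses 10,000 replicates of
  18-year series; mixed-model recovery uses 200 replicates of 3 groups
  × 6 species × 18 years; window-broadening recovery 200 simulated
  single-species stations. These sizes give Monte-Carlo error
  comfortably below the asserted tolerances while keeping the default
  suite around a minute.

## Known limitations

* Wald z inference for mixed-model contrasts is slightly liberal for
  few species per group; interpret borderline p-values with the sweep
  brackets, not as sharp thresholds.
* The window metric compounds two threshold crossings, so its sampling
  noise is roughly double that of the peak; window trends need more
  years for the same power.
* Peak dates are integer days; slopes below ~0.05 d/yr are not
  resolvable over 18 years.
* The <5-captures exclusion and the 10% threshold are the study's
  constants, configurable but not re-optimized here.
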