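# phenopass

Passage-timing analysis for constant-effort bird ringing stations.

Long-term ringing stations on migration flyways produce daily capture
counts that, once standardized by trapping effort, trace each species'
seasonal passage wave. `phenopass` turns those records into annual
phenology metrics and multi-year trend comparisons: it answers whether a
species' spring passage is advancing, by how many days per year, and
whether species that winter in different regions (North Africa, the
Sahel, tropical Africa) are shifting at different rates — the kind of
question at the heart of climate-change phenology monitoring.

## The method

For each species *s* and year *y*:

1. **CPUE standardization.** Daily captures are converted to catch per
   unit of effort, `CPUE_d = 100 · n_d / (L_d · H_d)` (captures per 100
   net-metre-hours, with `L_d` metres of net and `H_d` hours open).
   Closure days are *missing*, never zero.
2. **Smoothing.** A centred 7-day moving average `MA(d)` over calendar
   days, skipping missing days, shrinking at the season edges.
3. **Phenology metrics.** Peak date = argmax `MA` (earliest on ties).
   Start/end of the main migration period = the nearest days flanking
   the peak with `MA < 0.1 · MA(peak)`; window = end − start. If the
   season begins (ends) with `MA` still at or above the threshold, the
   start (end) is *undefined* and flagged truncated. Species-years with
   fewer than 5 captures are excluded.
4. **Per-species trends.** OLS of each annual metric on year:
   `m_{sy} = a_s + b_s · y + ε`; the slope `b_s` (days/year, negative =
   advance) with its SE and two-sided t-test.
5. **Group comparison.** Linear mixed model over species pooled by
   wintering group *g*:
   `m_{sy} = β₀ + β_g + (β_year + β_{g:year}) · y + u_s + ε_{sy}`,
   with `u_s ~ N(0, τ²)` a species random intercept (REML). The marginal
   slope of group *g* is `β_year + β_{g:year}`, tested by Wald z;
   pairwise slope contrasts are summarized by a compact letter display
   (insert-and-absorb) across a sweep of significance levels, reporting
   non-significant contrasts as a bracketed p-range.
6. **Sex-specific analysis** for dimorphic species: the same per-species
   and mixed-model machinery applied separately to males and females and
   to sex × year interactions within groups (protandry trends).

A simulator generates multi-year station datasets — effort-scaled
Poisson counts from Gaussian passage waves whose mean (and optionally
spread) drifts linearly — so every stage can be validated against known
ground truth.

## Worked example

```python
import phenopass as pp

cfg = pp.default_config(seed=1)          # 18 years, 30 species, 3 groups
ds = pp.simulate_station_dataset(cfg)

cpue = pp.daily_cpue_table(ds.captures, ds.effort,
                           species=list(ds.species_meta["species"]))
metrics = pp.PhenologyExtractor().fit_transform(cpue)
merged = metrics.merge(ds.species_meta[["species", "wintering_group"]],
                       on="species")
cmp_ = pp.GroupTrendComparator(metric="peak").fit(merged)
print(cmp_.marginal_slopes_.round(3).to_string(index=False))
```

prints

```
       group  slope    se      z  p_value
North Africa -0.729 0.074 -9.876    0.000
       Sahel -0.521 0.052 -9.944    0.000
    Tropical -0.049 0.052 -0.945    0.344
```

i.e. the model-implied peak-date trend per wintering group in days per
year: simulated North-African and Sahel winterers advance by ~0.7 and
~0.5 days/year (both p < 0.001) while the tropical group is flat — and
these recover the generating trends (−0.8, −0.5, −0.1) of the default
configuration. The fitted letter display at α = 0.05 is
`{'North Africa': 'a', 'Sahel': 'b', 'Tropical': 'c'}`: all three
groups' slopes separate. Per-species trends, sex-specific analyses and
tidy reports come from the `SpeciesTrendEstimator`, `sex_group_analysis`
and the CLI:

```sh
phenopass all --simulate --seed 1 --out run/   # full pipeline + manifest
phenopass extract --captures cap.csv --effort eff.csv \
    --species-meta meta.csv --out metrics.csv  # on your own data
```

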