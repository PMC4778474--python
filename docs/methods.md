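# Methods

## The scientific problem

Semi-captive working Asian elephants (*Elephas maximus*) live in a tropical
monsoon climate with a strongly seasonal work schedule, and their
population-level birth and death rates are themselves highly seasonal.  The
pipeline asks whether two monthly physiological markers — faecal
glucocorticoid metabolite concentration (GCM, ng/g dry faeces; a
non-invasive proxy for stress-hormone load) and body weight (kg; a proxy
for condition) — track climate (rainfall, temperature) and the demographic
cycle, and with what time shift.  Every stage operates on 12-slot
calendar-month series: the year is a cycle, and December–January adjacency
is physically real.

## Data model and the synthetic generator

The study data are registry data that are not publicly deposited, so the
package ships a generator that emulates their structure; all statistical
claims made by the test suite are claims about data with this structure.

For individual *i*, variable *v* and calendar month *m* the panel model is

    y_ivm = β_v(sex_i, age_i) + b_iv + A_v cos(2π (m − φ_v) / 12) + ε_ivm

* `β_v` — baseline.  Weight baselines are multiplicative per sex × age
  cell: adult female 2500 kg, males ×1.26, oldest age class (≥45 y)
  ×1.075.  The GCM baseline is 50 ng/g for all cells.
* `b_iv ~ N(0, σ²_ind,v)` — individual random intercept
  (σ_ind = 12 ng/g for GCM, large relative to its seasonal amplitude;
  150 kg for weight, small relative to its baseline — mirroring the
  qualitative finding of large between-individual variation in GCM but low
  variation in weight).
* single-harmonic seasonality: amplitude A = 15 ng/g peaking in July for
  GCM (months June–August highest), A = 60 kg peaking in September for
  weight (July–October highest, one month after the rainfall peak).  One
  harmonic is the minimal structure that gives lag-recovery tests a
  well-defined ground truth.
* `ε` — stationary AR(1): ε_m = φ ε_{m−1} + η_m, φ = 0.3 by default
  (month-to-month carryover; φ = 0 disables it), innovation SD 8 ng/g /
  30 kg.

Sampling design defaults: 75 focal animals (43 female) measured every
month for GCM; weight measured only for adults (> 16 y), only in 10
calendar months (August and November missing), supplemented by 51
weight-only adults from three other camps, giving ≈ 116 weight animals.
Age-class mix 13 % / 60 % / 27 % (≤16 / 17–44 / ≥45 years).

Climate is a deterministic climatology: rainfall is a truncated cosine
(base 300 mm, amplitude 600 mm, peak August → 0–900 mm with a rainless
December–April), temperature an untruncated cosine (24 ± 10 °C peaking
April–May).

Demography is monthly Poisson counts over 53 years: birth intensity is a
single harmonic with January peak, July trough and max/min ratio 1.8
(mean 3.7 births/month ≈ 2350 births over the period); death intensity is
a hand-set 12-vector peaking in January and bottoming in November with
ratio 2.0 (≈ 1040 deaths), because a peak and trough 10 months apart
cannot be represented by one harmonic.  Demography is generated as counts,
not individual life histories: downstream analysis consumes only monthly
profiles.

What the generator does **not** emulate: pregnancy effects and their
exclusion at collection time, growth in juveniles, camp-specific work
schedules, between-year climate variation, age-dependent vital rates, and
any dependence of demographic events on the physiology of specific
individuals.  Passing tests therefore demonstrate the statistical
machinery's correctness and calibration on data with the assumed
structure, not the biological conclusions of any particular study
population.

## Preparation

* **Within-individual centering** — deviation = value − individual's own
  mean over its observed months.  (One published convention states the
  subtraction the other way; the `negate` flag flips the sign, which
  affects nothing but the sign of downstream correlations.)  Individuals
  with a single observation carry no within-subject information: dropped
  from centering, logged, but retained for monthly means.
* **Monthly group means** — arithmetic means per calendar month within
  sex × age-group cells.  The pooled series is the *unweighted* mean of
  the per-group monthly means, so month-to-month changes in group
  composition (which month has more juveniles sampled, etc.) do not
  distort the seasonal profile.  Months with no data propagate as missing;
  nothing is imputed.
* **Demographic profiles** — mean events per calendar month across years;
  the max/min month ratio quantifies seasonality and is reported as
  missing (never an error) when the minimum month has zero events.
* **Z-scores** — (x − mean)/SD over non-missing months, SD with n−1; used
  only for overlay output, since Spearman statistics are rank-based and
  unaffected.

## Month-effect test

The repeated-measures month effect is tested with an F-like ratio
(between-month mean square / within-month mean square) computed on centred
values, calibrated by permuting month labels independently *within* each
individual.  This scheme destroys seasonal alignment across animals while
exactly preserving each animal's value multiset — hence all
between-individual heterogeneity — so the test is exact under
within-individual exchangeability, which holds when the residual process
is iid.  With genuine AR(1) residuals within-individual exchangeability is
only approximate; the test suite calibrates type-I error at φ = 0.

This replaces a REML linear-mixed-model / corARMA analysis deliberately:
the centred-value formulation is the robustness variant of that analysis,
needs no correlation-structure selection, and its null calibration can be
verified by simulation.  No AIC model selection, REML estimation or
interaction testing is performed.  The permutation statistic has no
mixed-model degrees of freedom; it is reported descriptively with its
permutation p.  p-values use the add-one estimator
(1 + #{null ≥ obs}) / (1 + n_perm), so the smallest attainable value is
1/(n_perm + 1); default n_perm = 10 000.

Group contrasts (male vs female weight, oldest vs prime-age females) are
percent differences of per-individual means — one value per animal, so
repeated measures do not inflate n — with a seeded percentile bootstrap
over individuals (default 2000 resamples, 95 %).

## Lagged cross-correlation

For series *a* and *b* and lag *k*, month *m* of *a* is paired with month
*m + k* of *b*; **k > 0 means b follows a by k months**.  Spearman's ρ
(Pearson on midranks) is computed over complete pairs after pairwise
deletion; the best lag maximizes |ρ| (strong negative correlations —
births against GCM — are as meaningful as positive ones), with ties broken
toward smaller |lag| (parsimony) and then the negative lag.

* **Alignment** — circular by default (the series are annual
  climatologies, so shifting wraps December into January); truncated mode
  drops out-of-range months and exists for sensitivity analysis.
* **Allowed lags** encode directionality: deaths may follow but never
  precede the marker ({0..+K}); the marker may follow but never precede
  climate ({0..+K} with climate first); births allow both signs
  ({−K..+K}) because a birth also marks a conception ~22 months earlier
  (gestation ≈ 22 months, so birth month − 22 mod 12 is the conception
  month, reported alongside); marker–marker pairs are unconstrained.
  Default K = 3.
* **Significance** — permutation of the 12 calendar slots of the second
  series, a held fixed: per-lag two-sided p for |ρ_k|, and a
  selection-adjusted p for max over allowed lags of |ρ|, which is the
  honest p-value when the best lag is chosen post hoc (the per-lag p at
  the selected lag over-rejects).  Both use add-one estimators; default
  n_perm = 10 000.  When both series are complete and alignment is
  circular, the null is computed vectorized (ranking commutes with slot
  permutation, so each null ρ is a dot product of permuted midranks);
  otherwise each permutation is recomputed with pairwise deletion, since
  permuting a series also permutes its missingness pattern.  A Student-t
  approximation p for a single Spearman ρ is provided for comparison only;
  it is crude at n = 12 and adjusts for nothing.
* **Degenerate inputs** — lags with fewer than 3 complete pairs or
  constant ranks are dropped with a warning; an empty lag set is an error.
  Permutations that produce a degenerate lag contribute ρ = 0 to the null
  (uninformative), a conservative choice that cannot manufacture
  significance.

## Pipeline

`run_pipeline` chains the stages on one seed: generation, series
preparation, two month-effect tests, and nine cross-correlation pairs
(GCM–weight; each marker against rainfall, temperature, births, deaths).
Marker–births pairs use the adult-female-only series (births are an
adult-female outcome); all other pairs use the pooled sex/age-balanced
series.  All downstream stages consume the stage files written to disk, so
a `--resume` run (which skips completed stages) is bit-identical to the
original, and `report.md` / `report.json` are deterministic functions of
(config, seed) — timestamps live only in `manifest.json`.  Stage seeds are
drawn from a dedicated child stream of the config seed, so adding a stage
does not reshuffle the others.

## Problem sizes and numerical choices

The test suite uses the study-scale design (75 GCM / ~116 weight
individuals) where the property under test depends on it (power,
lag-recovery), and smaller panels elsewhere; permutation counts in tests
are 99–999, chosen so that Monte Carlo error is small relative to the
asserted tolerances (the null-calibration checks use 1000 replicate
datasets, giving a standard error of ~0.007 on a 0.05 rejection rate).
Oracle comparisons (naive rank-then-Pearson, exhaustive lagged-pair
construction) are asserted to 1e-12; ρ is clamped to [−1, 1] against float
excursions, and permutation tail counts use a 1e-12 tie guard so that
discrete rank statistics equal to the observed value count as exceedances
(conservative).

## Known limitations

* The month-effect permutation test is exact under iid residuals but only
  approximate under strong within-individual autocorrelation.
* With n = 12 months, Spearman ρ takes few distinct values; permutation
  p-values are correspondingly granular, and the smallest attainable
  selection-adjusted p is limited by the 12! slot permutations.
* The cross-correlation null permutes calendar slots, which destroys the
  autocorrelation of the permuted series; for strongly autocorrelated
  series the per-lag p-values are anti-conservative in the usual way, which
  is one reason the selection-adjusted statistic is the headline p.
* Circular versus truncated alignment is a genuine modelling choice; both
  are provided, and results for short series can differ between them.
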