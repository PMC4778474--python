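# eleseason

Seasonal analysis of stress physiology, body condition, climate and
demography in semi-captive working Asian elephants — and, more generally, a
toolkit for asking whether monthly biological time series follow the same
annual cycle, and with what time shift.

It is written for wildlife endocrinologists and population ecologists who
have (a) repeated monthly measurements of a physiological marker on known
individuals, (b) long-run monthly birth/death records, and (c) a monthly
climatology, and who want the analysis chain:

1. **within-individual centering** of the longitudinal panel, isolating each
   animal's seasonal deviations from stable between-animal differences;
2. a **permutation month-effect test** on the centred values: an F-like
   ratio (between-month MS / within-month MS) calibrated by permuting month
   labels within each individual, which respects the repeated-measures
   structure without any parametric correlation model;
3. **monthly demographic profiles** (mean births/deaths per calendar month
   across years, with max/min seasonality ratios);
4. **sign-constrained lagged Spearman cross-correlation**: for calendar
   month series *a*, *b* and lag *k* (pairing a(m) with b(m+k), wrapping
   December into January), ρ(k) is the Pearson correlation of midranks over
   complete pairs; the best lag maximizes |ρ(k)| over a lag set that
   encodes directionality (deaths may follow but not precede a marker;
   a marker may follow but not precede climate; births allow both signs
   because a birth also marks a conception ~22 months earlier). Permutation
   of the calendar slots gives per-lag p-values and a selection-adjusted
   p-value for max|ρ| that accounts for the best lag being chosen post hoc.

Because the motivating study's registry data are not publicly deposited,
the package includes a first-class synthetic generator
(individual random intercepts, single-harmonic seasonality, AR(1)
month-to-month noise, structured missingness, Poisson demographic
seasonality) so the entire pipeline is exercisable and testable from a
single seed. See `docs/methods.md` for the model and all defaults.

## Worked example

```sh
eleseason run --out-dir run --seed 1 --n-perm 4999
```

or equivalently from Python:

```python
from eleseason import run_pipeline
run_pipeline(out_dir="run", seed=1, n_perm=4999)
```

generates a study-scale dataset (75 focal animals measured monthly for GCM,
~116 adults for weight with August/November unobserved, 53 years of
demography) and writes `run/report.md`. With seed 1 the cross-correlation
table reads:

```
| pair               | best lag | rho    | p (per-lag) | p (selection-adjusted) |
| gcm_weight         | +2       | 0.988  | 0.0002      | 0.0002                 |
| gcm_rainfall       | +0       | 0.812  | 0.0036      | 0.0096                 |
| gcm_births         | +0       | -0.923 | 0.0002      | 0.0008                 |
| weight_rainfall    | +1       | 0.982  | 0.0002      | 0.0002                 |
| weight_deaths      | +0       | -0.821 | 0.0064      | 0.018                  |
```

Read: glucocorticoid metabolites rise and fall with rainfall in the same
month (ρ = 0.81); body weight tracks rainfall with a one-month delay
(ρ = 0.98 at lag +1 — the configured truth, since the generated weight
peak sits one month after the rainfall peak); months with high
adult-female GCM are months with few births (ρ = −0.92); and weight is
low in high-mortality months (ρ = −0.82). The selection-adjusted p is the
honest significance level given that the lag was picked to maximize |ρ|.
The same run reports the month-effect tests (GCM statistic 164.3,
p = 2×10⁻⁴ at 4999 permutations — the smallest attainable value),
demographic seasonality (birth max/min ratio 1.92, death ratio 2.29) and
covariate contrasts (adult males +26.8 % heavier than females,
95 % bootstrap CI [+24.1, +29.5]).

Individual stages are exposed as subcommands (`generate`, `prep`,
`seasonality`, `xcorr`) and as plain functions (`gen_panel`,
`center_within_individual`, `monthly_group_means`, `month_effect_test`,
`lagged_xcorr`, `xcorr_significance`, ...).

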