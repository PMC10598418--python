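# Methods

## Data model

The unit of observation is the trossa: a tier of gillnets set once and
hauled once. Records carry trip and boat identifiers, set/haul dates, mean
set depth (m), net geometry (length × number of nets × height), a deterrent
flag, per-species bird and mammal bycatch counts and the lumpfish count.
Soak time is measured in whole days with a minimum of one; the unit of
effort throughout is the *standardised trossa-day* — net area × soak days /
2000 m². Soaks longer than the 3-day regulatory maximum are flagged by the
validator but not rejected (the regulation allows exceedance in bad
weather). Species labels are free strings; groupings such as "all birds" or
"common and black guillemot" are configuration, not code, because analyses
mix single species and aggregates.

Depth bins are half-open `[lower, upper)` with a final open bin (default
10 m bins up to >50 m); a depth exactly on an edge belongs to the deeper
bin. Bin rates are pooled (Σ counts / Σ effort), not means of per-trossa
rates, so bin rate × bin effort always reconstructs the raw count; bins with
no effort are NaN, never a silent zero.

## Deterrent-effect bootstrap

Controls are matched within the fishing trip only, by drawing a target depth
from Normal(deterrent depth, 5 m) and taking the same-trip control closest
to it. The target is not truncated at zero (only relative distance matters);
ties in closeness are broken uniformly at random, implemented as iid
tie-breaking noise of order 1e-9 m added to the distances — far below any
real depth difference. The same control may serve several pairs within an
iteration, since matching is independent per draw.

Per iteration the statistic is the median over pairs of (a) device rates,
(b) control rates, (c) paired differences. With this construction the
median difference need not equal median(device) − median(control) — the
pattern the trial's published effect table shows — and a
`difference-of-medians` alternative is exposed on `BootstrapConfig` without
asserting which construction any particular study used. Estimates are
summarised as medians and 2.5%/97.5% quantiles over iterations (default
10 000); significance means the difference interval excludes zero.

Determinism and order-independence: records are resampled via a list sorted
by record content, so permuting dataset order cannot change an estimate at a
fixed seed; each species group gets its own seed stream derived from the
root seed and a stable hash of the group name, so adding or removing a group
never perturbs another group's result.

With realistically sparse bycatch (>80% zero-bycatch trossas) the
per-iteration medians are typically zero, and the interval for the
difference degenerates to (0, 0) — which *covers* zero. Calibration is
therefore near-conservative under the null; power against an injected
80% reduction is essentially complete once the baseline reaches about one
bird per standardised trossa-day, and negligible an order of magnitude
below that. The published per-group medians themselves are not reproducible
without the raw trial database, so the estimator is tested by its
statistical properties against generator ground truth, not by value.

## Landings-to-effort extrapolation and restriction scenarios

Annual landings (tons) convert to fish at an assumed 3 kg per gravid female.
Bin effort is tons × bin landings proportion × 1000 / 3 / bin catch rate;
annual bycatch is Σ effort × bird rate. Published rate tables print bycatch
rates at two decimals, which distorts sparse bins by up to ~20%
(0.0122 → 0.01); where the per-bin annual bycatch column is available the
package divides it by the derived effort to recover unrounded rates, and the
scenario engine uses these by default. The unrounded rates reproduce the
published restriction projections to within ±3 individuals and ±2 t.

"Redistribution in equal proportion to the available greater depths" is
implemented as equal absolute shares: banned effort ÷ number of open bins
added to each open bin. The alternative — reallocation proportional to each
open bin's existing effort — is provided but is not the default, because
only equal shares reproduces the published projections (e.g. ≈4876 vs ≈5050
birds for a >10 m restriction). Total effort is conserved to 1e-9 relative;
restriction depth must coincide with a bin edge and depth 0 reproduces the
baseline exactly. Mammal projections are emitted only relative to baseline:
trial-area mammal bycatch is known not to be representative fleet-wide.
Note the relative mammal changes are computed from the printed 2-decimal
mammal rates (no per-bin mammal bycatch column exists to unround them), so
they are the least precise output of the engine.

Year series: projections are linear in tonnage at fixed depth proportions,
so the mean over years equals the mean-year projection; per-year min–max
ranges are reported from whatever landings series the caller supplies.
Year-specific depth proportions default to the multi-year mean proportions.

## Synthetic fleet generator

The generator is the ground-truth oracle for the estimators, emulating the
trial's design: 7 boats, 84 trips of 5–16 trossas (mean 10.5), exactly one
deterrent trossa in each of 61 randomly chosen trips, soaks uniform on 1–3
days, areas triangular on (993.2, 2169.1, 2837.7) m² — the mode chosen so
the mean is exactly 2000 m². Depths are drawn per trossa around a per-trip
centre (centre ~ Normal(25, 8) m, within-trip SD 8 m, clipped to 5–60 m):
this places >80% of effort at 10–40 m while leaving enough within-trip depth
spread for depth matching to be meaningful. The within-trip spread is a
modelling choice, not an observed quantity.

Counts: birds and mammals are Poisson with mean rate(depth) × standardised
effort (bird rates optionally gamma-mixed for clumping); lumpfish are
negative-binomial via a gamma-Poisson mixture with shape `fish_dispersion`
(default 3, i.e. variance ≈ μ + μ²/3 — strongly overdispersed, as commercial
catch data are). The deterrent multiplier applies to bird rates only; the
generator's default of 1.0 encodes no effect, and fish and mammals are never
affected, matching the a-priori expectation for an above-water visual
deterrent. Bird counts are split into species multinomially using the
trial's reported species totals (151/250 common eider, etc.). Default rate
functions are the published depth-specific step rates, under which the
expected bird total (~218) sits within 25% of the trial's observed 250.

`expected_totals` gives the analytic mean of the generator: expected effort
factorises (area, soak and depth independent), while the depth expectation
of a rate function has no closed form under the doubly clipped normal depth
model and is integrated numerically with a fixed internal quasi-random draw
(200 000 points, error ≪ the Monte-Carlo tolerances it is compared at).

What the generator does *not* emulate: spatial autocorrelation, seasonality,
boat-level skill differences, and bird-density fields — depth is the only
covariate driving rates. Passing recovery/coverage tests therefore shows the
estimators are correct under the stated model, not that real fleets satisfy
that model.

## Numerical and testing choices

- Problem sizes in the replicated tests are chosen to keep the full suite
  around a quarter of a minute: bootstrap property tests use 1000 iterations
  per replicate (coverage and power are insensitive to the iteration count
  at these scales), null-coverage runs 200 study-scale replicates, power 100,
  and generator mean-agreement 500 replicates of a 20-trip fleet.
- Flat per-bin tolerances are statistically meaningless for sparse-bin bird
  rates (a 0.01 birds/trossa-day bin yields ~15 expected birds even at
  10 000 trossas, Poisson CV ≈ 26%), so rate-recovery tests use 5% where
  counts support it and a 3-standard-error envelope otherwise.
- CSV round-trips are bit-exact: floats are written with `repr`, dates as
  ISO-8601, booleans as `true`/`false`; record equality treats an absent
  species count and an explicit zero as identical.
- The pipeline writes a manifest (seed, config hash, artifact list) with
  every run; rerunning with the same seed reproduces the effect and scenario
  tables byte for byte.

## Known limitations

- Published per-group bootstrap medians cannot be checked by value without
  the raw trial records; only distributional properties are asserted.
- Range floors of published scenario tables are not asserted: the printed
  floors imply a minimum-year tonnage below the stated landings minimum,
  suggesting year-specific depth proportions that are not public.
- The scenario engine assumes catch rates at depth are maintained when
  effort moves deeper and that fleet-level effort is conserved; economic
  feasibility of fishing deeper is out of scope.
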