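# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package.  It documents what the code computes; every
empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Data contract and calendar policy

Daily weather carries eight candidate predictors with fixed units
(T °C, H %, Rf mm, Cc %, Sd h, Ws km/h, Wd °, Wg km/h).  Units are part
of the contract because regression coefficients are unit-dependent.
Missing days or out-of-range values are hard errors at ingest; an
optional linear-interpolation repair (off by default) exists for
interior gaps, since real station records are rarely complete.

Days are numbered 1-based within the calendar year (8 March = 67 in
common years).  Cross-year alignment — climatological means for a fixed
calendar date, and fixed averaging windows — is keyed by (month, day);
29 February is excluded from all cross-year aggregation so that window
lengths stay comparable between leap and common years.  Within-season
forcing sums, by contrast, run over actual calendar days and therefore
include 29 February: heat accumulates on real days.  Pollen
concentrations absent from the record are treated as missing, recorded
zeros as true zeros.

## Season definitions

The start day under criterion f ∈ {2.5%, 5%} is the first day whose
running cumulative sum (from 1 January) reaches f of the **full
calendar-year** total; using the calendar-year total matches the
standard main-pollen-season definitions, and the choice matters little
here because the spring season carries almost all of the annual sum.
The peak day is the earliest argmax within days 1–181 (configurable);
restricting the search prevents a secondary late-summer rise from
capturing the maximum.  "Reaches" is `>=` in both definitions.

## Linear regression pipeline

* Candidate windows: all (start, end) pairs with starts 1 Jan–25 Feb and
  ends 1 Mar–11 Mar (56 × 11 = 616) for start-day models; for peak-day
  models, 56 start dates with the end resolved per year to that year's
  observed season start, plus the start day itself as a ninth candidate
  feature.  All eight variables are aggregated by plain arithmetic mean,
  including rainfall and wind direction: a uniform rule keeps the
  coefficient semantics consistent, and circular averaging for Wd was
  rejected because the models treat Wd linearly.
* Variable selection is greedy forward stepwise on adjusted R².  Exact
  ties break by the canonical order T, H, Cc, Sd, Ws, Wd, Wg, Rf.  An
  exhaustive best-subset mode exists for comparison; on orthogonal
  designs the two provably agree and the tests check this.
* Selection runs once per window on the full training set; the selected
  variables are then refitted in leave-one-year-out folds and the final
  coefficients are the arithmetic fold means.  Re-selecting variables
  inside each fold would make coefficient averaging ill-defined across
  differing variable sets.  Fold fits need only point estimates, so an
  exact fit with zero residual degrees of freedom is legal inside folds,
  while the full inferential fit requires n > p + 1.
* The significance gate applies the overall model F-test (p ≤ 0.05),
  not per-coefficient tests.  The score of a window is the out-of-fold
  MAE on day-rounded predictions; the admissible window with the
  smallest score wins, earlier windows winning ties through the fixed
  enumeration order.
* Predicted days are rounded half-away-from-zero to whole days
  everywhere (67.4 → 67, 90.623 → 91); the rounding rule is stated
  because it changes MAEs by up to half a day.
* Peak-day models are trained with each year's **observed** season
  start (as window end and as feature) and predict with the
  **predicted** start — the only causally consistent combination at
  forecast time.

## Phenological pipeline

Start model: sigmoid forcing `1/(1 + exp(d·(tavg − c)))` accumulated
daily from onset F1; flowering when the sum reaches M.  The verbal
threshold reading ("heat counts only above c") is realised by the
sigmoid itself — terms vanish well below c — with no extra hard cutoff,
which would contradict the formula.  Peak model: clamped degree-days
`max(Tavg − Th, 0)` from the first day strictly after the season start
with Tavg ≥ T_D; contributions are clamped at zero so cold days never
erase accumulated heat.

Calibration grids: F1 over every calendar day 1 Oct–28 Feb (151 values,
autumn onsets borrowing the preceding year's weather); d over
−10…−0.25 in steps of 0.25 (40 values — zero is excluded since d must
be negative); c, T_D, Th over 0…40 °C in 1 °C steps.  Per-year units
accumulate **to the observed start day inclusive** (the alternative,
exclusive, accumulation is one argument away) and, for the peak, from
the observed start to the observed peak.  Filters: mean units must
exceed ε = 10⁻⁶ (the "non-zero forcing" rule) and the relative SD
(sample SD, ddof = 1, over mean) must not exceed 50%.  Survivors are
scored by training MAE, predicting each training year with the
candidate's own mean units M under pure observed weather (no blend) —
selection and hindcasting are kept separate.  Ties break by smaller
RSD, then by parameter order (F1 chronological from 1 Oct, then d, c /
T_D, Th), so results are independent of evaluation order.  A survivor
whose threshold is never crossed in some training year carries an
infinite training MAE and can never be selected.

The grid evaluation is vectorised (shared cumulative-sum arrays per
(d, c) pair with `searchsorted` threshold crossings); the full start
grid on 12 years runs in a few seconds.  The scalar operations
`sigmoid_forcing_sum`/`heat_sum` are the reference semantics, and the
tests pin the vectorised grid to a plain brute-force enumeration over
those scalars on a mini-grid.

Prediction scans from F1 (or from the trigger day after the given
start) to 30 June; failing to reach M by then is an explicit
"no crossing" error rather than a silent extreme date.

## Hindcast blend

For days after the issue date (default 25 Feb) the value used is
`w_obs × observed + w_hist × climatology` with defaults 0.8/0.2, the
climatology being the training-year mean for that calendar date.  The
blend applies to all eight variables uniformly.  It uses the year's own
later observations, so it is an evaluation device emulating a
short-range forecast, not an operational forecast.  With w_obs = 1 the
entire pipeline provably reduces to pure observation, and the tests
check this end-to-end.  A post-issue 29 February has no climatology key
and keeps its observation.  Daily forecast updating is obtained by
re-running prediction with the issue date advanced one day at a time.

## Synthetic data generator

The generator defines the study conditions: 15 scored seasons
(2004–2018) with the weather starting 1 Oct 2003, because the earliest
grid onset needs the preceding autumn; a 12/3 chronological train/test
split mirrors an 80/20 convention.  Daily temperature is
`20.3 − 11·cos(2π·doy/365)` plus AR(1) noise (ρ = 0.7, innovation SD
1.5 °C), giving an Islamabad-like annual mean of 20.3 °C, January near
9–10 °C and mid-summer near 31 °C.  The other variables follow simple
bounded models (anti-phase humidity, Bernoulli–exponential rain with
15% wet days, gamma wind speed, uniform direction, gust proportional to
speed) — enough structure to exercise selection, not a climate model.

Pollen release inverts the forcing equations with truth parameters
inside the searched grids: F1 = 31 Jan, d = −0.25, c = 15 °C,
M_start = 14.7; T_D = 16 °C, Th = 11 °C, M_peak = 34 °C·day.  The two
requirements were set to match plausible Islamabad forcing totals and
to put the mean start near 8 March (the generated mean is day 68).
Each season is a 45-day skewed bell with maximum 40,000 grains/m³ at
the true peak: a concave square-root rise from the true start to the
peak, then an exponential decay with time constant a quarter of the
remaining season.  A pure lognormal bell was rejected because its
shallow onset put too little mass in the first two days, letting the
5% criterion drift more than two days past the true start; with the
chosen kernel the noiseless 5% start stays within two days of truth and
the noiseless argmax equals the true peak exactly.  Multiplicative
lognormal noise with configurable CV (default 0.15) perturbs
concentrations; an optional small summer bump is off by default.
Ground-truth start*/peak* days are computed with independent per-day
loops, not the pipeline's vectorised code, so parameter recovery is a
genuine dual-route check.

What the generator does **not** emulate: observation gaps and detection
limits, multi-sampler spatial variation, humidity/rain suppression of
pollen release, the real bimodal summer season, or weather–pollen
feedbacks beyond temperature.  Passing tests therefore demonstrate that
the pipelines recover known forcing structure and rank models sensibly,
not that the same accuracy would hold on real Islamabad counts.

## Problem sizes and determinism

Defaults: 616 windows × 12 training years for the regression search
(tens of seconds), 247,640 start-grid combinations (seconds,
vectorised), reduced window/grid ranges in the quick examples and in
most tests.  All randomness flows through seeded NumPy generators;
fixed config and seed give byte-identical reports, and the orchestration
passes only training-year slices to any fitting routine (a tamper test
perturbs the test years and checks the fitted models are unchanged).

## Known limitations

* The regression search refits ~50 small OLS models per window; on much
  longer series or denser window grids a precomputed sufficient-statistics
  scheme would be preferable.
* The p ≤ 0.05 gate is applied per window without multiplicity control
  across the 616 windows; with a pure-noise response some window can
  still pass by chance, so the gate limits, but does not eliminate,
  selection bias (the cross-validated window score is the main guard).
* Reference Islamabad coefficient sets are shipped for the prediction
  path; applied to synthetic weather they demonstrate mechanics, not
  calibrated accuracy.
* Season end days (95%/97.5%), summer-season prediction and
  chilling/photoperiod terms are out of scope.
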