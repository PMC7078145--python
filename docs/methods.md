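# Methods

## Model and assumptions

A floating carcass faces three mutually exclusive daily fates: beach within
the searched area (probability `f`), be permanently lost (`ω`), or remain
afloat (`S`), with `S + f + ω = 1`. The fate process is a discrete-time
absorbing Markov chain: a carcass released on day `i` beaches on day `j`
(age `a = j − i + 1`) with probability `P(i,j) = f_[class] · Π S_[class]`
over the `a − 1` days it stayed afloat. Beaching is possible on the release
day itself (`b₁ = f`); the alternative convention requiring one survival
interval first is *not* used. The per-cohort multinomial over
`(recovery day i..D, never recovered)` gives the dead-recovery likelihood;
the m-array of cohort × recovery-day counts is its sufficient statistic.

Implicit assumptions (shared with the band-recovery literature): fates are
independent across carcasses and days; all carcasses in a parameter class
share the same daily probabilities; recoveries are recorded on the true
beaching day; release day, not calendar covariates, drives the process
(no wind/current covariates are modelled).

Parameter structures may be constant, fully time-dependent (one value per
calendar study day), or age-dependent with contiguous age classes (release
day = age 1, last class open-ended). The 14-member candidate set combines:
the constant model; reduced age-class beaching structures
({1},{2+} … {1},{2},{3},{4},{5+}, plus two variants with pooled early
classes — `f(age-4 w/1st 2 "age" classes = 2 days)` is read as
{1–2},{3–4},{5},{6+}); age-structured survival ({1},{2},{3+} and full age);
and fully time/age-dependent models.

## Estimation

- **Links and optimizer.** Each parameter has an independent logit link
  (so `S + f ≤ 1` is not enforced during the search; a clipped
  never-recovered probability yields a large finite penalty outside the
  valid region, and `ω < 0` is flagged post-fit). Link values are capped at
  |logit| ≤ 15 to keep boundary fits finite; cap hits are flagged.
  Optimization is L-BFGS-B with the analytic gradient of the multinomial
  log-likelihood, from a moment-style start (S from the mean recovery age,
  f from the recovered fraction) plus jittered multi-starts (default 5,
  N(0, 0.5) on the link scale, seeded).
- **Likelihood convention.** Multinomial coefficients are omitted
  (constant in the parameters). The saturated −2 log L uses empirical cell
  proportions under the same convention, so deviances and AICc differences
  are unaffected; absolute −2 log L values are comparable only within this
  convention.
- **Uncertainty.** The observed information is the central-difference
  Hessian of the negative log-likelihood at the optimum (step 1e−5 on the
  link scale, differencing the analytic gradient). Wald intervals are
  logit-scale estimate ± z·SE back-transformed to (0, 1); parameters in a
  numerically singular information direction get NaN intervals.
- **Identifiable parameter count K (used in AICc).** Parameters estimated
  at the link boundary were driven there by the data (e.g. zero recoveries
  in an at-risk class) and count as estimated parameters. Among interior
  parameters, K adds the number of eigenvalues of the information sub-block
  above 1e−6 × its largest (configurable). This drops genuinely confounded
  combinations — in fully time-dependent structures the terminal-day S and
  f enter only as a product — and classes whose likelihood is entirely flat
  because no carcass was ever at risk in them (those stay interior with
  ~zero curvature). A pure full-spectrum eigenvalue count was rejected: a
  capped logit has curvature ~1e−7, so boundary-heavy models would escape
  the AICc penalty and dominate model selection on data generated under the
  constant model.
- **AICc.** `AICc = −2 log L + 2K + 2K(K+1)/(n−K−1)` with `n` = total
  carcasses released. Akaike weight = normalized `exp(−Δ/2)`; ties broken
  by smaller K, then name.

## Goodness of fit

Parametric bootstrap of the deviance: simulate B datasets from the fitted
model with the same release schedule (per-cohort multinomial draws), refit,
and report `P = (1 + #{dev_b ≥ dev_obs}) / (B + 1)` (default B = 1000).
Calibration: on densely observed designs (cells with expected counts well
above 1) the deviance is approximately pivotal and the test holds its
nominal level. On sparse designs like the 35-day reference study — 27
recoveries scattered over hundreds of cells — the observed deviance is
dominated by the number of recoveries, which the fitted `f` reproduces in
the bootstrap draws; observed and bootstrap deviances are therefore
positively correlated and the test is **conservative** (P values
concentrate near 0.5, and true lack of fit is flagged less often than α
suggests). P values on such designs are descriptive, not exact.

## Synthetic data

The simulator draws one categorical fate per carcass per day (not
aggregated multinomials), so individual encounter histories exist for the
sensitivity perturbations; carcasses still afloat at day D are censored as
never recovered. It is bit-reproducible given (config, seed).

The reference configuration emulates the Gulf of Mexico drift experiment:
D = 35 daily occasions; 195 carcasses; constant S = 0.829, f = 0.0242
(ω = 0.1468, β = 0.1415). The per-date release counts were not published
beyond "13 dates in a 23-day span", so the default splits 15 carcasses on
each of days {1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 23} — an even
spread over the span; any other 13-way split is configurable. The spatial
release grid is collapsed to counts per day (the model has no spatial
terms). What the simulator does *not* emulate: wind/current-driven drift,
spatially clustered beaching, date-specific environmental shocks, imperfect
detection of beached carcasses, and recording error in arrival dates.
Passing tests therefore validate the estimation machinery under the model's
own assumptions, not the field realism of those assumptions.

## Sensitivity operations

All act on individual encounter records and are rerun through the full
candidate analysis:

- `shift_arrivals(k)` — every recovery day moved `k` days earlier, floored
  at the release day (arrival before first ground contact).
- `reclassify_to_lost(ids)` — beached records demoted under a stricter
  findability standard.
- `reclassify_to_beached(id, day)` — a lost record promoted (a beaching
  the crews missed).
- `transmitter_failure(rate, seed)` — removes `round(rate × n)` randomly
  chosen never-recovered records entirely. Failed transmitters are
  indistinguishable from losses, so affected carcasses shrink the release
  denominator rather than standing as true losses; this mechanism raises
  the beaching estimate by ≈ 1/(1 − rate), consistent with reported
  failure-rate analyses. The magnitude of the arrival shift is exposed as
  a parameter (the original analyses did not state theirs).

## Numerical choices and problem sizes

Tolerances: optimizer ftol 1e−12 / gtol 1e−8; cell-closure identity holds
to 1e−12; likelihood m-array/individual-record equivalence to 1e−10;
identifiability threshold 1e−6 (relative); infinite-horizon β switches to
the geometric closed form once all structures reach their terminal age
class. Degenerate inputs: `f ≡ 0` gives a never-recovered probability of 1
and β = 0; datasets with no recoveries drive `f̂` to the link cap with a
boundary flag; `S = 1` with `f > 0` makes the infinite-horizon β undefined
(error).

Simulation-based validation uses: 500 replicates for parameter recovery
and CI coverage; 100 replicates of the full 14-model analysis (2 starts
per fit) for selection consistency; 200 outer replicates with B = 200 on a
dense 6-occasion design for GOF calibration; the acceptance script
averages fitted fate probabilities over 40 replicate studies.

## Known limitations

- The conservativeness of the bootstrap GOF on sparse designs (above).
- Wald-on-logit intervals can be poor for `f` near 0 in small samples;
  profile likelihood intervals are not implemented.
- β's sampling uncertainty is not propagated by default (the point
  estimate is derived from the fitted parameters; a parametric-simulation
  propagation hook exists but is off by default).
- Fully time-dependent models on a single-cohort-per-day design are
  heavily over-parameterized; their fits are reported but their K depends
  on the boundary/rank convention described above.
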